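"""Reading, combining and writing protein intensity tables.

Input tables are delimited text with a header row, one row per protein:
an identifier column plus one non-negative intensity column per labeling
channel (e.g. iTRAQ reporter channels 114/115/116/117). Intensities are
assumed to have been summarized from peptide to protein level upstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Cell contents treated as a missing intensity (case-insensitive).
MISSING_MARKERS = ("", "na", "nan")

COMPARISON_COLUMNS = ["protein_id", "A", "M", "sigma2", "Z", "P", "P_adj"]
INTEGRATION_COLUMNS = [
    "protein_id",
    "k",
    "best_P",
    "second_best_P",
    "avg_Z",
    "avg_Z_P",
    "avg_Z_P_adj",
    "fdr_second_best",
    "fdr_avg_z",
]


@dataclass
class ProteinProfile:
    """Per-run protein-level intensities, one column per labeling channel.

    ``intensities`` is indexed by protein identifier; a NaN cell means the
    channel was not observed for that protein (missing, not zero).
    """

    run_id: str
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if self.intensities.shape[1] < 1:
            raise ValueError("a profile needs at least one channel column")
        dup = self.intensities.index[self.intensities.index.duplicated()]
        if len(dup):
            raise ValueError(
                "duplicate protein identifiers: " + ", ".join(map(str, dup.unique()))
            )
        values = self.intensities.to_numpy(dtype=float)
        if np.any(values[np.isfinite(values)] < 0):
            raise ValueError("negative intensities are not allowed")

    @property
    def n_proteins(self) -> int:
        return self.intensities.shape[0]

    @property
    def channels(self) -> list[str]:
        return [str(c) for c in self.intensities.columns]


@dataclass
class ConditionPair:
    """Combined per-condition intensities over a shared protein universe.

    Every retained protein has strictly positive intensity in both
    conditions, so log2 ratios are finite. ``n_dropped`` counts proteins
    removed because their combined intensity was zero (or absent) in at
    least one condition.
    """

    ids: np.ndarray
    a: np.ndarray
    b: np.ndarray
    label_a: str = "A"
    label_b: str = "B"
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if not (len(self.ids) == len(self.a) == len(self.b)):
            raise ValueError("ids and the two intensity vectors must be aligned")
        if len(pd.unique(self.ids)) != len(self.ids):
            raise ValueError("duplicate protein identifiers in condition pair")
        for label, values in ((self.label_a, self.a), (self.label_b, self.b)):
            bad = ~(values > 0) | ~np.isfinite(values)
            if bad.any():
                raise ValueError(
                    f"non-positive intensity in condition {label!r} for "
                    + ", ".join(map(str, self.ids[bad][:5]))
                )

    def __len__(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"protein_id": self.ids, self.label_a: self.a, self.label_b: self.b}
        )


def load_profile_table(
    path: str | Path,
    id_column: str,
    channel_columns: Sequence[str] | None = None,
    delimiter: str = "\t",
    run_id: str | None = None,
) -> ProteinProfile:
    """Read one run's protein intensity table.

    Parameters
    ----------
    path:
        Delimited text file with a header row (UTF-8).
    id_column:
        Name of the protein identifier column.
    channel_columns:
        Intensity columns to load; ``None`` loads every non-id column.
    delimiter:
        Field separator (tab by default, ``","`` for CSV exports).

    Empty cells and ``NA``/``NaN`` markers are stored as absent (NaN),
    never as zero. Duplicate identifiers and negative intensities raise.
    """
    path = Path(path)
    table = pd.read_csv(
        path,
        sep=delimiter,
        dtype=str,
        keep_default_na=False,
        skipinitialspace=True,
    )
    if id_column not in table.columns:
        raise ValueError(f"id column {id_column!r} not found in {path.name}")
    if channel_columns is None:
        channel_columns = [c for c in table.columns if c != id_column]
    missing_cols = [c for c in channel_columns if c not in table.columns]
    if missing_cols:
        raise ValueError(
            f"channel column(s) {', '.join(missing_cols)} not found in {path.name}"
        )
    if not channel_columns:
        raise ValueError("no channel columns to load")

    raw = table[list(channel_columns)].apply(lambda s: s.str.strip())
    missing = raw.apply(lambda s: s.str.lower().isin(MISSING_MARKERS))
    data = raw.apply(pd.to_numeric, errors="coerce")
    # cells that were non-numeric text but not a recognized missing marker
    unparsed = (data.isna() & ~missing).to_numpy()
    if unparsed.any():
        row = int(np.argwhere(unparsed)[0, 0])
        raise ValueError(f"unparseable intensity value in data row {row + 1}")
    negative = (data < 0).to_numpy()
    if negative.any():
        row = int(np.argwhere(negative)[0, 0])
        raise ValueError(f"negative intensity in data row {row + 1}")

    ids = table[id_column].astype(str)
    dup = ids[ids.duplicated()].unique()
    if len(dup):
        raise ValueError("duplicate protein identifiers: " + ", ".join(dup))
    data.index = pd.Index(ids, name=id_column)
    return ProteinProfile(run_id=run_id or path.stem, intensities=data)


def combine_channels(
    profile: ProteinProfile, groups: Mapping[str, Sequence[str]]
) -> ConditionPair:
    """Sum labeling channels into two condition profiles.

    ``groups`` maps exactly two condition labels to their channel lists
    (e.g. ``{"undiff": ["114", "115"], "diff": ["116", "117"]}``). A
    channel absent for a protein contributes 0 to the sum; proteins whose
    combined intensity is 0 in either condition are dropped and counted.
    """
    if len(groups) != 2:
        raise ValueError("exactly two condition labels are required")
    for label, channels in groups.items():
        unknown = [c for c in channels if c not in profile.intensities.columns]
        if unknown:
            raise ValueError(
                f"unknown channel(s) for condition {label!r}: {', '.join(unknown)}"
            )
        if not channels:
            raise ValueError(f"condition {label!r} lists no channels")

    (label_a, chans_a), (label_b, chans_b) = groups.items()
    sum_a = profile.intensities[list(chans_a)].sum(axis=1, skipna=True).to_numpy()
    sum_b = profile.intensities[list(chans_b)].sum(axis=1, skipna=True).to_numpy()
    keep = (sum_a > 0) & (sum_b > 0)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info(
            "%s: dropped %d protein(s) with zero combined intensity in at "
            "least one condition",
            profile.run_id,
            n_dropped,
        )
    if not keep.any():
        raise ValueError("no protein has positive combined intensity in both conditions")
    return ConditionPair(
        ids=profile.intensities.index.to_numpy(dtype=object)[keep],
        a=sum_a[keep],
        b=sum_b[keep],
        label_a=str(label_a),
        label_b=str(label_b),
        n_dropped=n_dropped,
    )


def _result_frame(result) -> pd.DataFrame:
    table = getattr(result, "table", result)
    if not isinstance(table, pd.DataFrame):
        raise TypeError("expected a result object or DataFrame")
    for columns in (COMPARISON_COLUMNS, INTEGRATION_COLUMNS):
        if set(columns).issubset(table.columns):
            return table[columns]
    raise ValueError("result table does not match a known column layout")


def write_results(result, path: str | Path, delimiter: str = "\t") -> None:
    """Write a comparison or integration result as a delimited table.

    Columns are emitted in a fixed order; numbers are serialized at full
    ``repr`` precision so a write/read round trip is lossless.
    """
    frame = _result_frame(result)
    # shortest round-trip representation of a double
    frame.to_csv(
        path, sep=delimiter, index=False, float_format=lambda v: repr(float(v))
    )


def read_results(path: str | Path, delimiter: str = "\t") -> pd.DataFrame:
    """Read back a table produced by :func:`write_results`."""
    table = pd.read_csv(
        path, sep=delimiter, dtype={"protein_id": str}, float_precision="round_trip"
    )
    return table
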