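"""Synthetic intensity tables with the statistical structure the model assumes.

Each protein gets a mean log2 intensity A drawn uniformly over a wide
dynamic range; its null log2 ratio is N(0, exp(theta1 + theta2 * A)), so
low-abundance proteins are noisier, as in isobaric-labeling MS data. A
configurable fraction of proteins is spiked with a fixed-magnitude log2
shift, split evenly between up and down so the spikes do not bias the
global normalization. Intensities are back-solved on the raw scale:

    S1 = 2**(A + M/2),    S2 = 2**(A - M/2),

which inverts exactly to the drawn (A, M). Multi-run studies share the
protein universe, abundances and spike labels, draw independent noise per
run, and can drop a random protein fraction per run to emulate partial
detection. The generator does not emulate ratio compression,
peptide-level variation or intensity-dependent missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_tables import ConditionPair, ProteinProfile


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the generator; the seed is mandatory.

    theta1/theta2 parameterize the true variance function
    exp(theta1 + theta2 * A) over the abundance range ``a_range`` (log2
    units). ``dep_fraction`` of proteins receive a log2 shift of
    magnitude ``dep_effect`` with balanced random signs.
    """

    seed: int
    n_proteins: int = 5000
    a_range: tuple[float, float] = (10.0, 25.0)
    theta1: float = 2.0
    theta2: float = -0.4
    dep_fraction: float = 0.0
    dep_effect: float = 1.5
    n_runs: int = 1
    dropout: float = 0.0
    technical_replicate: bool = False

    def __post_init__(self) -> None:
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be positive")
        if not 0.0 <= self.dep_fraction < 1.0:
            raise ValueError("dep_fraction must be in [0, 1)")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")
        if not self.a_range[0] < self.a_range[1]:
            raise ValueError("a_range must be increasing")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.dep_effect < 0:
            raise ValueError("dep_effect must be non-negative")

    def variance_at(self, a_values) -> np.ndarray:
        return np.exp(self.theta1 + self.theta2 * np.asarray(a_values, dtype=float))


@dataclass
class SimulatedPair:
    """One simulated comparison plus its ground truth.

    ``truth`` columns: protein_id, A, sigma2_true, is_dep, effect, M.
    ``profile`` is a 4-channel table (two technical-replicate channels per
    condition) when the config asks for it.
    """

    pair: ConditionPair
    truth: pd.DataFrame
    profile: ProteinProfile | None = None


@dataclass
class SimulatedStudy:
    """Multi-run simulation sharing protein universe and spike labels."""

    runs: list[SimulatedPair]
    truth: pd.DataFrame  # per-protein shared ground truth (A, is_dep, effect)


def _draw_population(cfg: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_proteins
    ids = np.array([f"P{i:06d}" for i in range(1, n + 1)], dtype=object)
    a = rng.uniform(cfg.a_range[0], cfg.a_range[1], size=n)
    is_dep = np.zeros(n, dtype=bool)
    effect = np.zeros(n)
    n_dep = int(round(cfg.dep_fraction * n))
    if n_dep:
        dep_idx = rng.choice(n, size=n_dep, replace=False)
        is_dep[dep_idx] = True
        signs = np.ones(n_dep)
        signs[: n_dep // 2] = -1.0
        effect[dep_idx] = cfg.dep_effect * rng.permutation(signs)
    return pd.DataFrame(
        {
            "protein_id": ids,
            "A": a,
            "sigma2_true": cfg.variance_at(a),
            "is_dep": is_dep,
            "effect": effect,
        }
    )


def _technical_profile(
    cfg: SimulationConfig,
    ids: np.ndarray,
    s1: np.ndarray,
    s2: np.ndarray,
    rng: np.random.Generator,
    run_id: str,
) -> ProteinProfile:
    """Split each condition into two technical-replicate channels.

    Within a condition the two channels carry the half-intensity plus a
    null log2 ratio drawn from the same variance function evaluated at the
    channel-level abundance, so comparing the two channels of one
    condition is an exact null comparison.
    """
    data = {}
    for cond, total, labels in (("a", s1, ("114", "115")), ("b", s2, ("116", "117"))):
        a_chan = np.log2(total / 2.0)
        m_tech = rng.normal(0.0, np.sqrt(cfg.variance_at(a_chan)))
        data[labels[0]] = 2.0 ** (a_chan + m_tech / 2.0)
        data[labels[1]] = 2.0 ** (a_chan - m_tech / 2.0)
    frame = pd.DataFrame(data, index=pd.Index(ids, name="protein_id"))
    return ProteinProfile(run_id=run_id, intensities=frame)


def simulate_pair(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    population: pd.DataFrame | None = None,
    run_id: str = "run1",
) -> SimulatedPair:
    """Simulate one two-condition comparison.

    ``population`` (shared A / spike labels) is drawn internally unless a
    multi-run driver passes one in. Same seed, same table: the generator
    is deterministic.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    if population is None:
        population = _draw_population(cfg, rng)
    a = population["A"].to_numpy()
    sigma2 = population["sigma2_true"].to_numpy()
    m = rng.normal(0.0, np.sqrt(sigma2)) + population["effect"].to_numpy()
    s1 = 2.0 ** (a + m / 2.0)
    s2 = 2.0 ** (a - m / 2.0)
    ids = population["protein_id"].to_numpy(dtype=object)
    pair = ConditionPair(ids=ids, a=s1, b=s2, label_a="cond1", label_b="cond2")
    truth = population.copy()
    truth["M"] = m
    profile = None
    if cfg.technical_replicate:
        profile = _technical_profile(cfg, ids, s1, s2, rng, run_id)
    return SimulatedPair(pair=pair, truth=truth, profile=profile)


def simulate_multi_run(cfg: SimulationConfig) -> SimulatedStudy:
    """Simulate ``n_runs`` comparisons with shared spike labels.

    Noise is independent across runs; with ``dropout`` > 0 each run
    independently loses that fraction of proteins (detection is then a
    Binomial(n_runs, 1 - dropout) per protein).
    """
    rng = np.random.default_rng(cfg.seed)
    population = _draw_population(cfg, rng)
    runs = []
    for t in range(cfg.n_runs):
        sim = simulate_pair(cfg, rng=rng, population=population, run_id=f"run{t + 1}")
        if cfg.dropout > 0:
            keep = rng.random(cfg.n_proteins) >= cfg.dropout
            sim = SimulatedPair(
                pair=ConditionPair(
                    ids=sim.pair.ids[keep],
                    a=sim.pair.a[keep],
                    b=sim.pair.b[keep],
                    label_a=sim.pair.label_a,
                    label_b=sim.pair.label_b,
                ),
                truth=sim.truth.loc[keep].reset_index(drop=True),
                profile=sim.profile,
            )
        runs.append(sim)
    return SimulatedStudy(runs=runs, truth=population)


def pair_to_table(sim: SimulatedPair) -> pd.DataFrame:
    """Raw-scale intensity table in the dialect ``load_profile_table`` reads.

    Four channel columns when a technical-replicate profile was generated,
    otherwise one combined intensity column per condition.
    """
    if sim.profile is not None:
        table = sim.profile.intensities.reset_index()
        table = table.rename(columns={table.columns[0]: "protein_id"})
        return table
    return sim.pair.to_frame()
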