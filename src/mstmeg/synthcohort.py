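"""Synthetic cohorts with planted envelope coupling and a linked biomarker.

No public MEG + plasma dataset accompanies the analysis this package
implements, so every downstream stage is exercised on synthetic data whose
ground truth is known by construction:

* **Region signals.**  For each frequency band, region ``i`` emits
  ``envelope_i(t) * carrier_i(t)``.  The envelope mixes a shared and an
  idiosyncratic smooth positive process,
  ``z_i = sqrt(c) * z_shared + sqrt(1 - c) * z_i'`` (unit-variance,
  standardized smoothed rectified Gaussian noise, low-passed below the
  band's lower edge), so the planted envelope correlation between any two
  regions equals the coupling ``c``.  Carriers are narrow-band cosines with
  independent random frequency and phase per region and epoch: zero-lag
  amplitude coupling is present while zero-lag phase coupling is negligible,
  which is exactly the regime leakage correction must tolerate.
* **Cohort.**  Per-subject couplings are drawn around ``coupling_base`` and
  the biomarker (pg/ml) follows a linear-plus-Gaussian link,
  ``biomarker = mean + effect_size * (c_s - coupling_base) + N(0, noise_sd)``.
  The first ``n_fhpos`` subjects carry the higher-risk group label.

Every generator is a pure function of (spec, seed): the same spec yields a
bitwise-identical cohort.  Toy trees and random unique-weight matrices with
known topology are provided for oracle tests of the tree stage.
"""
from __future__ import annotations

from collections.abc import Iterator
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.signal import firwin, filtfilt

from .connectivity import ConnectivityMatrix
from .signal import (ALPHA, BETA, DEFAULT_FILTER_ORDER, THETA, BandSpec,
                     EpochedTimeSeries)
from .tree import SpanningTree

GROUP_HIGH_RISK = "FH+"
GROUP_LOW_RISK = "FH-"

#: Depth of the envelope modulation around its unit mean.
ENVELOPE_DEPTH = 0.25
#: Floor keeping envelopes strictly positive after modulation.
ENVELOPE_FLOOR = 0.05
#: Per-subject couplings are clipped to this closed range.
COUPLING_RANGE = (0.0, 0.9)
#: Biomarker values are floored here to respect positivity (pg/ml).
BIOMARKER_FLOOR = 1.0


def effect_size_for_correlation(rho: float, coupling_sd: float,
                                noise_sd: float) -> float:
    """Effect size that plants a biomarker-coupling correlation of ``rho``.

    From the linear link, corr = e*sd_c / sqrt(e^2 sd_c^2 + sd_n^2), hence
    e = sd_n * rho / (sd_c * sqrt(1 - rho^2)).
    """
    if not 0 <= rho < 1:
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    if rho == 0:
        return 0.0
    return noise_sd * rho / (coupling_sd * np.sqrt(1.0 - rho ** 2))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults reproduce the study-scale conditions: 76 subjects (54 labelled
    higher-risk), 80 regions, 30 epochs of 4096 samples at 1000 Hz, and an
    effect size planting a biomarker-coupling correlation of 0.5 given the
    default coupling spread and biomarker noise.
    """

    n_subjects: int = 76
    n_fhpos: int = 54
    n_regions: int = 80
    n_epochs: int = 30
    epoch_samples: int = 4096
    fs: float = 1000.0
    bands: tuple[BandSpec, ...] = (THETA, ALPHA, BETA)
    coupling_base: float = 0.35
    coupling_sd: float = 0.15
    effect_size: float = 577.35   # pg/ml per unit coupling; plants corr 0.5
    noise_sd: float = 150.0       # pg/ml
    biomarker_mean: float = 381.7  # pg/ml
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError(f"n_subjects must be >= 1, got {self.n_subjects}")
        if not 0 <= self.n_fhpos <= self.n_subjects:
            raise ValueError(
                f"n_fhpos must be in [0, n_subjects], got {self.n_fhpos}")
        if self.n_regions < 3:
            raise ValueError(f"n_regions must be >= 3, got {self.n_regions}")
        if self.n_epochs < 1:
            raise ValueError(f"n_epochs must be >= 1, got {self.n_epochs}")
        if self.epoch_samples * self.n_epochs < DEFAULT_FILTER_ORDER * 4:
            raise ValueError(
                "epoch_samples * n_epochs must be at least four times the "
                f"filter order ({DEFAULT_FILTER_ORDER}); got "
                f"{self.epoch_samples} * {self.n_epochs}")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not 0 <= self.coupling_base < 1:
            raise ValueError(
                f"coupling_base must be in [0, 1), got {self.coupling_base}")
        if self.coupling_sd < 0:
            raise ValueError(f"coupling_sd must be >= 0, got {self.coupling_sd}")
        if self.noise_sd < 0:
            raise ValueError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for band in self.bands:
            band.validate_against(self.fs)

    @classmethod
    def test_profile(cls, **overrides) -> "CohortSpec":
        """Scaled-down profile keeping the full pipeline at desk runtime:
        20 subjects, 10 regions, 10 epochs of 1024 samples at 250 Hz."""
        defaults = dict(n_subjects=20, n_fhpos=14, n_regions=10, n_epochs=10,
                        epoch_samples=1024, fs=250.0,
                        bands=(THETA, ALPHA, BETA))
        defaults.update(overrides)
        return cls(**defaults)


class ToyTreeKind(Enum):
    STAR = "star"
    PATH = "path"
    Y_TREE = "y_tree"
    RANDOM_UNIQUE_WEIGHTS = "random_unique_weights"


def _as_rng(rng: np.random.Generator | int | None) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def _smooth_standard_envelope(rng: np.random.Generator, shape: tuple[int, ...],
                              n_samples: int, fs: float,
                              f_env: float) -> np.ndarray:
    """Standardized smoothed rectified Gaussian noise (zero mean, unit sd)."""
    raw = np.abs(rng.standard_normal(shape + (n_samples,)))
    numtaps = int(2 * fs / f_env) | 1
    b = firwin(numtaps, f_env, fs=fs)
    z = filtfilt(b, [1.0], raw, axis=-1,
                 padlen=min(n_samples - 1, 3 * numtaps))
    sd = z.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return (z - z.mean(axis=-1, keepdims=True)) / sd


def _band_component(rng: np.random.Generator, spec: CohortSpec,
                    coupling: float, band: BandSpec
                    ) -> tuple[np.ndarray, np.ndarray]:
    """One band's (signal, planted envelope), both (R, E, T)."""
    R, E, T = spec.n_regions, spec.n_epochs, spec.epoch_samples
    f_env = band.low / 2.0
    z_shared = _smooth_standard_envelope(rng, (E,), T, spec.fs, f_env)
    z_own = _smooth_standard_envelope(rng, (R, E), T, spec.fs, f_env)
    z = np.sqrt(coupling) * z_shared[None] + np.sqrt(1.0 - coupling) * z_own
    env = np.clip(1.0 + ENVELOPE_DEPTH * z, ENVELOPE_FLOOR, None)
    margin = 0.1 * (band.high - band.low)
    freq = rng.uniform(band.low + margin, band.high - margin, (R, E))
    phase = rng.uniform(0.0, 2.0 * np.pi, (R, E))
    t = np.arange(T) / spec.fs
    carrier = np.cos(2.0 * np.pi * freq[..., None] * t + phase[..., None])
    return env * carrier, env


def generate_subject_timeseries(
    spec: CohortSpec,
    coupling: float,
    rng: np.random.Generator | int | None = None,
    return_truth: bool = False,
) -> EpochedTimeSeries | tuple[EpochedTimeSeries, dict[str, np.ndarray]]:
    """Region x epoch x sample signals with planted envelope coupling.

    The output sums one band-limited component per band in ``spec.bands``.
    With ``return_truth=True`` the planted (ground-truth) envelopes are
    returned as a dict keyed by band name — the oracle against which
    measured envelope correlations are compared.
    """
    if not 0 <= coupling < 1:
        raise ValueError(f"coupling must be in [0, 1), got {coupling}")
    spec.validate()
    rng = _as_rng(rng)
    data = np.zeros((spec.n_regions, spec.n_epochs, spec.epoch_samples))
    truth: dict[str, np.ndarray] = {}
    for band in spec.bands:
        sig, env = _band_component(rng, spec, coupling, band)
        data += sig
        truth[band.name] = env
    ts = EpochedTimeSeries(data=data, fs=spec.fs)
    if return_truth:
        return ts, truth
    return ts


def draw_cohort_table(spec: CohortSpec) -> pd.DataFrame:
    """Subject table with group labels, planted couplings and biomarker.

    Columns: subject_id, group, coupling_true, biomarker.  All draws come
    from the generator seeded by ``spec.seed``; the first ``n_fhpos``
    subjects are labelled higher-risk.
    """
    root = np.random.SeedSequence(spec.seed)
    rng = np.random.default_rng(root.spawn(1)[0])
    coupling = np.clip(
        rng.normal(spec.coupling_base, spec.coupling_sd, spec.n_subjects),
        *COUPLING_RANGE)
    biomarker = (spec.biomarker_mean
                 + spec.effect_size * (coupling - spec.coupling_base)
                 + rng.normal(0.0, spec.noise_sd, spec.n_subjects))
    biomarker = np.maximum(biomarker, BIOMARKER_FLOOR)
    group = np.array([GROUP_HIGH_RISK] * spec.n_fhpos
                     + [GROUP_LOW_RISK] * (spec.n_subjects - spec.n_fhpos))
    return pd.DataFrame({
        "subject_id": [f"sub_{i:03d}" for i in range(spec.n_subjects)],
        "group": group,
        "coupling_true": coupling,
        "biomarker": biomarker,
    })


def iter_cohort(
    spec: CohortSpec, return_truth: bool = False
) -> Iterator[tuple[pd.Series, EpochedTimeSeries] |
              tuple[pd.Series, EpochedTimeSeries, dict[str, np.ndarray]]]:
    """Yield (table row, time series[, truth]) per subject, lazily.

    Memory-friendly companion of :func:`generate_cohort`: study-scale
    subjects are large, so the pipeline writes each one to disk before
    generating the next.
    """
    table = draw_cohort_table(spec)
    root = np.random.SeedSequence(spec.seed)
    seeds = root.spawn(spec.n_subjects + 1)[1:]
    for i, row in table.iterrows():
        rng = np.random.default_rng(seeds[i])
        out = generate_subject_timeseries(spec, float(row.coupling_true), rng,
                                          return_truth=return_truth)
        if return_truth:
            ts, truth = out
            yield row, ts, truth
        else:
            yield row, out


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[EpochedTimeSeries], pd.DataFrame]:
    """Materialize the whole cohort in memory (small specs only)."""
    series = [ts for _, ts in iter_cohort(spec)]
    return series, draw_cohort_table(spec)


def make_toy_tree(kind: ToyTreeKind | str, n: int = 5,
                  rng: np.random.Generator | int | None = None) -> SpanningTree:
    """Canonical toy trees with known topology.

    star: one center (node 0) adjacent to all others; path: a chain;
    y_tree: the fixed 5-node tree with edges {1-2, 2-3, 2-4, 4-5} (1-based);
    random_unique_weights: uniformly random labelled tree (via a random
    Pruefer sequence) with all-distinct weights.
    """
    kind = ToyTreeKind(kind)
    if kind is ToyTreeKind.Y_TREE:
        if n != 5:
            raise ValueError("y_tree is defined on exactly 5 nodes")
        edges = [(0, 1, 1.0), (1, 2, 1.0), (1, 3, 1.0), (3, 4, 1.0)]
        return SpanningTree(n_nodes=5, edges=edges)
    if n < 3:
        raise ValueError(f"need n >= 3 nodes, got {n}")
    if kind is ToyTreeKind.STAR:
        edges = [(0, i, 1.0) for i in range(1, n)]
    elif kind is ToyTreeKind.PATH:
        edges = [(i, i + 1, 1.0) for i in range(n - 1)]
    else:  # RANDOM_UNIQUE_WEIGHTS
        rng = _as_rng(rng)
        pruefer = rng.integers(0, n, size=n - 2)
        pairs = _tree_from_pruefer(pruefer, n)
        weights = rng.permutation(np.linspace(0.1, 0.9, n - 1))
        edges = [(i, j, float(w)) for (i, j), w in zip(pairs, weights)]
    return SpanningTree(n_nodes=n, edges=edges)


def _tree_from_pruefer(seq: np.ndarray, n: int) -> list[tuple[int, int]]:
    """Decode a Pruefer sequence into the edge list of a labelled tree."""
    degree = np.ones(n, dtype=int)
    for v in seq:
        degree[v] += 1
    edges = []
    import heapq
    leaves = [i for i in range(n) if degree[i] == 1]
    heapq.heapify(leaves)
    for v in seq:
        leaf = heapq.heappop(leaves)
        edges.append((min(leaf, int(v)), max(leaf, int(v))))
        degree[v] -= 1
        if degree[v] == 1:
            heapq.heappush(leaves, int(v))
    a, b = heapq.heappop(leaves), heapq.heappop(leaves)
    edges.append((min(a, b), max(a, b)))
    return edges


def make_random_matrix(n: int, seed: int | np.random.Generator | None = 0
                       ) -> ConnectivityMatrix:
    """Symmetric matrix with all-distinct off-diagonal weights in (0, 1)."""
    if n < 3:
        raise ValueError(f"need n >= 3, got {n}")
    rng = _as_rng(seed)
    while True:
        vals = rng.uniform(0.0, 1.0, n * (n - 1) // 2)
        vals = vals[(vals > 0) & (vals < 1)]
        if len(vals) == n * (n - 1) // 2 and len(np.unique(vals)) == len(vals):
            break
    m = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    m[iu] = vals
    m += m.T
    return ConnectivityMatrix(values=m)
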