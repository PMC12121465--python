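"""Synthetic data with known ground truth for the circadian pipeline.

Three generators mirror the statistical structure the analysis modules
assume:

* damped-cosine reporter traces with treatment/washout epochs
  (PMT-like 0.1 h or imaging-like 0.5 h sampling);
* one-cycle SILAC-style proteome tables: 5 circadian timepoints
  (CT0/6/12/18/24, the last an independently resampled CT0) with 3
  replicates, a chosen fraction of rhythmic features, and missingness;
* cell x gene count matrices with typed cells, marker genes, a planted
  two-gene co-expression partition, and day/night expression differences.

Every generator takes a single integer seed; all randomness derives from it
and the same seed reproduces the output bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .traces import Trace

_PARTITION_CATEGORIES = ("neither", "a_only", "b_only", "both")


# ---------------------------------------------------------------------------
# trace generator
# ---------------------------------------------------------------------------

@dataclass
class EpochEffect:
    """Treatment-epoch modification of the underlying oscillation.

    ``amplitude_factor`` scales the oscillation amplitude inside the epoch;
    ``phase_offset_h`` shifts the oscillation phase from the epoch start
    onward (positive = advance, the peak arrives earlier); ``level_offset``
    adds a constant level inside the epoch.  After the epoch the amplitude
    returns to its pre-epoch envelope, exponentially with
    ``recovery_halflife_h`` if given, instantly otherwise.
    """

    start_h: float
    end_h: float
    amplitude_factor: float = 1.0
    phase_offset_h: float = 0.0
    level_offset: float = 0.0
    recovery_halflife_h: float | None = None

    def __post_init__(self) -> None:
        if self.start_h >= self.end_h:
            raise ValueError("epoch start must precede end")
        if self.amplitude_factor < 0:
            raise ValueError("amplitude_factor must be >= 0")


@dataclass
class TraceSimSpec:
    duration_h: float = 240.0
    dt_h: float = 0.1
    period_h: float = 24.0
    phase_h: float = 6.0
    amplitude: float = 1.0
    damping_per_cycle: float = 0.0
    drift_slope: float = 0.0
    drift_intercept: float = 0.0
    noise_sd: float = 0.0
    epochs: Sequence[EpochEffect] = field(default_factory=tuple)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt_h <= 0:
            raise ValueError("dt_h must be positive")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")
        if not 0 <= self.damping_per_cycle < 1:
            raise ValueError("damping_per_cycle must be in [0, 1)")
        if self.duration_h <= 2 * self.period_h:
            raise ValueError("duration_h must exceed two periods")
        spans = sorted((e.start_h, e.end_h) for e in self.epochs)
        for (_, b0), (a1, _) in zip(spans, spans[1:]):
            if a1 < b0:
                raise ValueError("epochs must be non-overlapping")


def _amplitude_envelope(t: np.ndarray, spec: TraceSimSpec) -> np.ndarray:
    env = spec.amplitude * (1.0 - spec.damping_per_cycle) ** (t / spec.period_h)
    factor = np.ones_like(t)
    for e in spec.epochs:
        inside = (t >= e.start_h) & (t < e.end_h)
        factor[inside] *= e.amplitude_factor
        after = t >= e.end_h
        if e.recovery_halflife_h is not None:
            rec = 1.0 - (1.0 - e.amplitude_factor) * 0.5 ** (
                (t[after] - e.end_h) / e.recovery_halflife_h
            )
            factor[after] *= rec
    return env * factor


def _phase_offset(t: np.ndarray, spec: TraceSimSpec) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    off = np.zeros_like(t)
    for e in spec.epochs:
        off[t >= e.start_h] += e.phase_offset_h
    return off


def simulate_trace(spec: TraceSimSpec) -> Trace:
    """Simulate a reporter trace; ground truth is attached as ``trace.truth``.

    The signal is ``drift + A(t) * cos(2pi (t - phase + offset(t)) / period)
    + level(t) + noise`` where a positive accumulated phase offset advances
    the oscillation.  Truth records the true period and the analytic peak
    times of the underlying (noise-free) oscillation.
    """
    t = np.arange(0.0, spec.duration_h + spec.dt_h / 2, spec.dt_h)
    rng = np.random.default_rng(spec.seed)
    env = _amplitude_envelope(t, spec)
    off = _phase_offset(t, spec)
    level = np.zeros_like(t)
    for e in spec.epochs:
        level[(t >= e.start_h) & (t < e.end_h)] += e.level_offset
    osc = env * np.cos(2 * np.pi * (t - spec.phase_h + off) / spec.period_h)
    value = spec.drift_intercept + spec.drift_slope * t + osc + level
    if spec.noise_sd > 0:
        value = value + rng.normal(0.0, spec.noise_sd, t.size)

    # analytic peak times: t = phase + m*period - accumulated offset, solved
    # per piecewise-constant offset segment by fixed-point iteration
    peak_times = []
    m = 0
    while True:
        pt = spec.phase_h + m * spec.period_h
        for _ in range(8):
            seg_off = float(_phase_offset(np.array([pt]), spec)[0])
            new = spec.phase_h + m * spec.period_h - seg_off
            if abs(new - pt) < 1e-12:
                break
            pt = new
        if pt > spec.duration_h:
            break
        if pt >= 0:
            peak_times.append(pt)
        m += 1

    if spec.epochs:
        first = min(spec.epochs, key=lambda e: e.start_h)
        last = max(spec.epochs, key=lambda e: e.end_h)
        epochs = {"baseline": (0.0, first.start_h), "treatment": (first.start_h, first.end_h)}
        if last.end_h < spec.duration_h:
            epochs["washout"] = (last.end_h, spec.duration_h)
    else:
        epochs = {"baseline": (0.0, spec.duration_h)}

    truth = {
        "true_period_h": spec.period_h,
        "true_peak_times_h": np.array(peak_times),
        "spec": spec,
    }
    return Trace(time_h=t, value=value, epochs=epochs, reporter="synthetic", truth=truth)


# ---------------------------------------------------------------------------
# proteome generator
# ---------------------------------------------------------------------------

@dataclass
class ProteomeSimSpec:
    n_proteins: int = 1000
    frac_rhythmic: float = 0.1
    timepoints: Sequence[float] = (0.0, 6.0, 12.0, 18.0, 24.0)
    n_replicates: int = 3
    peak_phases: Sequence[float] = (0.0, 6.0, 12.0, 18.0)
    rel_amplitude: float = 0.5
    noise_sd: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.frac_rhythmic <= 1:
            raise ValueError("frac_rhythmic must be in [0, 1]")
        tps = list(self.timepoints)
        if tps != sorted(tps) or len(set(tps)) != len(tps):
            raise ValueError("timepoints must be strictly increasing")
        if self.missing_rate >= 1 or self.missing_rate < 0:
            raise ValueError("missing_rate must be in [0, 1)")


def simulate_proteome(spec: ProteomeSimSpec):
    """Simulate a log2-ratio feature x (timepoint x replicate) table.

    Rhythmic features follow an additive cosine on the log2 scale with a
    peak phase drawn round-robin from ``peak_phases``; flat features are
    constant at zero.  The CT24 column re-evaluates the CT0 phase of the
    cosine (period 24 h) with an independent noise draw, emulating an
    independently repeated CT24/0 sample.  Returns ``(OmicsTimeTable,
    truth)`` where truth is a per-feature frame with ``is_rhythmic`` and
    ``peak_phase_h``.
    """
    from .rhythms import OmicsTimeTable

    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    n_rhythmic = int(round(spec.frac_rhythmic * n))
    phases = np.full(n, np.nan)
    phase_cycle = np.asarray(spec.peak_phases, dtype=float)
    phases[:n_rhythmic] = phase_cycle[np.arange(n_rhythmic) % phase_cycle.size]
    is_rhythmic = np.zeros(n, dtype=bool)
    is_rhythmic[:n_rhythmic] = True

    tps = np.asarray(spec.timepoints, dtype=float)
    base = np.zeros((n, tps.size))
    base[is_rhythmic] = spec.rel_amplitude * np.cos(
        2 * np.pi * ((tps[None, :] % 24.0) - phases[is_rhythmic, None]) / 24.0
    )

    values = np.repeat(base[:, :, None], spec.n_replicates, axis=2)
    if spec.noise_sd > 0:
        values = values + rng.normal(0.0, spec.noise_sd, values.shape)
    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    feature_ids = [f"P{i:05d}" for i in range(n)]
    columns = [
        f"CT{int(t) if float(t).is_integer() else t}_rep{r + 1}"
        for t in tps
        for r in range(spec.n_replicates)
    ]
    data = pd.DataFrame(
        values.reshape(n, -1), index=pd.Index(feature_ids, name="feature_id"),
        columns=columns,
    )
    table = OmicsTimeTable(data)
    truth = pd.DataFrame(
        {"is_rhythmic": is_rhythmic, "peak_phase_h": phases},
        index=data.index,
    )
    return table, truth


# ---------------------------------------------------------------------------
# cell x gene generator
# ---------------------------------------------------------------------------

@dataclass
class CellTypeSpec:
    name: str
    proportion: float
    marker_genes: Sequence[str] = ()


@dataclass
class CoexprPairSpec:
    """Planted joint expression pattern of two genes.

    ``probs`` maps cell-type name to the four partition probabilities
    (p_neither, p_a_only, p_b_only, p_both), each summing to 1.
    """

    gene_a: str
    gene_b: str
    probs: dict

    def __post_init__(self) -> None:
        for name, p in self.probs.items():
            if len(p) != 4 or abs(sum(p) - 1.0) > 1e-9:
                raise ValueError(f"partition probabilities for {name!r} must sum to 1")


@dataclass
class CellSimSpec:
    cell_types: Sequence[CellTypeSpec]
    n_cells: int = 2000
    n_genes: int = 200
    baseline_mean: float = 2.0
    dispersion: float = 2.0
    marker_fold: float = 8.0
    coexpr_pair: CoexprPairSpec | None = None
    day_fraction: float = 0.5
    day_night_lfc: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(ct.proportion for ct in self.cell_types)
        if abs(total - 1.0) > 1e-9:
            raise ValueError("cell-type proportions must sum to 1")


def _gene_universe(spec: CellSimSpec) -> list[str]:
    named: list[str] = []
    for ct in spec.cell_types:
        named.extend(g for g in ct.marker_genes if g not in named)
    if spec.coexpr_pair is not None:
        for g in (spec.coexpr_pair.gene_a, spec.coexpr_pair.gene_b):
            if g not in named:
                named.append(g)
    for g in spec.day_night_lfc:
        if g not in named:
            named.append(g)
    if len(named) > spec.n_genes:
        raise ValueError("n_genes smaller than the number of named genes")
    taken = set(named)
    fillers: list[str] = []
    i = 0
    while len(named) + len(fillers) < spec.n_genes:
        g = f"Gene{i:04d}"
        if g not in taken:
            fillers.append(g)
        i += 1
    return named + fillers


def simulate_cells(spec: CellSimSpec):
    """Simulate a typed cell x gene count matrix.

    Counts are negative binomial with mean ``baseline_mean`` (markers of a
    cell's own type scaled by ``marker_fold``, day/night genes scaled by
    half the log2 fold either side) and dispersion ``dispersion``
    (variance = mean + mean^2 / dispersion).  The planted co-expression pair
    is forced to the sampled partition category (zeroed, or at least one
    count).  Returns a :class:`~clockworks.cells.CellGeneMatrix` whose
    ``truth`` frame records type, partition category and day/night label.
    """
    from .cells import CellGeneMatrix

    rng = np.random.default_rng(spec.seed)
    genes = _gene_universe(spec)
    gene_index = {g: i for i, g in enumerate(genes)}
    for ct in spec.cell_types:
        for g in ct.marker_genes:
            if g not in gene_index:
                raise ValueError(f"marker gene {g!r} not in gene universe")

    # integer cell counts per type, largest-remainder rounding
    props = np.array([ct.proportion for ct in spec.cell_types])
    raw = props * spec.n_cells
    n_per = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - n_per))[: spec.n_cells - n_per.sum()]:
        n_per[i] += 1

    type_of = np.repeat([ct.name for ct in spec.cell_types], n_per)
    n = type_of.size

    means = np.full((n, len(genes)), float(spec.baseline_mean))
    row = 0
    for ct, k in zip(spec.cell_types, n_per):
        idx = [gene_index[g] for g in ct.marker_genes]
        means[row : row + k, idx] *= spec.marker_fold
        row += k

    is_day = rng.random(n) < spec.day_fraction
    for g, lfc in spec.day_night_lfc.items():
        j = gene_index[g]
        means[is_day, j] *= 2.0 ** (lfc / 2.0)
        means[~is_day, j] *= 2.0 ** (-lfc / 2.0)

    r = spec.dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p)

    categories = np.array(["unconstrained"] * n, dtype=object)
    if spec.coexpr_pair is not None:
        ja = gene_index[spec.coexpr_pair.gene_a]
        jb = gene_index[spec.coexpr_pair.gene_b]
        for ct_name in np.unique(type_of):
            probs = spec.coexpr_pair.probs.get(ct_name)
            if probs is None:
                continue
            rows = np.flatnonzero(type_of == ct_name)
            draw = rng.choice(4, size=rows.size, p=probs)
            categories[rows] = np.array(_PARTITION_CATEGORIES, dtype=object)[draw]
            a_on = (draw == 1) | (draw == 3)
            b_on = (draw == 2) | (draw == 3)
            counts[rows, ja] = np.where(a_on, np.maximum(counts[rows, ja], 1), 0)
            counts[rows, jb] = np.where(b_on, np.maximum(counts[rows, jb], 1), 0)

    barcodes = pd.Index([f"cell{i:05d}" for i in range(n)], name="cell_id")
    counts_df = pd.DataFrame(counts, index=barcodes, columns=genes)
    truth = pd.DataFrame(
        {
            "cell_type": type_of,
            "partition_category": categories,
            "time_label": np.where(is_day, "day", "night"),
        },
        index=barcodes,
    )
    return CellGeneMatrix(
        counts=counts_df,
        cell_type=truth["cell_type"],
        time_label=truth["time_label"],
        truth=truth,
    )
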