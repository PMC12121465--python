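"""Circadian calling on one-cycle, replicated, low-frequency time courses.

The experimental design this module targets is a single circadian cycle
sampled at CT0, 6, 12, 18 and 24 h (CT24 being an independently collected
repeat of the CT0 phase) with a few replicates per timepoint.  Two
rank-based tests are run per feature:

* a JTK-style test: Kendall's tau (tau-b tie convention) between the
  observations and a cosine reference evaluated at each observation's
  timepoint, maximized over a grid of candidate peak lags;
* an umbrella test (RAIN-style alternative): a Jonckheere-Terpstra-type
  statistic summing Mann-Whitney counts along the rise to a candidate peak
  and the fall after it, maximized over candidate peaks.

Both tests share one permutation engine: observations are permuted across
timepoint slots and the tail probability of the max-over-candidates
statistic is taken, which makes the p-values exactly valid for this design
and absorbs the lag/peak multiplicity.  Enumeration is exhaustive when the
number of distinct assignments is small, Monte-Carlo with a fixed seed
otherwise.  A feature is called circadian when *both* tests reject at the
chosen alpha (no across-feature multiplicity correction).

Both statistics are linear in the pairwise comparison matrix of the
observations, so for complete, tie-free features the permutation null
depends only on the slot layout and is computed once per table rather than
once per feature.
"""

from __future__ import annotations

import itertools
import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

_COLUMN_RE = re.compile(r"^CT(?P<ct>[0-9]+(?:\.[0-9]+)?)_rep(?P<rep>[0-9]+)$")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

class OmicsTimeTable:
    """Feature x (timepoint x replicate) table of log2 abundance ratios.

    Columns follow the ``CT{t}_rep{r}`` dialect; NaN marks a missing value.
    """

    def __init__(self, data: pd.DataFrame):
        parsed = {}
        for col in data.columns:
            m = _COLUMN_RE.match(str(col))
            if not m:
                raise ValueError(f"column {col!r} does not match 'CT<t>_rep<r>'")
            parsed[col] = (float(m["ct"]), int(m["rep"]))
        if np.isinf(data.to_numpy(dtype=float)).any():
            raise ValueError("table values must be finite (NaN marks missingness)")
        self.data = data.astype(float)
        self._col_ct = parsed
        self.timepoints = sorted({ct for ct, _ in parsed.values()})

    @property
    def feature_ids(self) -> pd.Index:
        return self.data.index

    def __len__(self) -> int:
        return len(self.data)

    def values_by_timepoint(self, feature_id) -> dict[float, np.ndarray]:
        """Non-missing replicate values per timepoint for one feature."""
        row = self.data.loc[feature_id]
        out: dict[float, list[float]] = {ct: [] for ct in self.timepoints}
        for col, (ct, _) in self._col_ct.items():
            v = row[col]
            if np.isfinite(v):
                out[ct].append(float(v))
        return {ct: np.asarray(vals) for ct, vals in out.items() if vals}

    def timepoint_means(self) -> pd.DataFrame:
        """Feature x timepoint matrix of replicate means (NaN-aware)."""
        groups: dict[float, list[str]] = {}
        for col, (ct, _) in self._col_ct.items():
            groups.setdefault(ct, []).append(col)
        return pd.DataFrame(
            {ct: self.data[cols].mean(axis=1) for ct, cols in sorted(groups.items())}
        )

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", na_rep="")

    @classmethod
    def from_tsv(cls, path) -> "OmicsTimeTable":
        return cls(pd.read_csv(path, sep="\t", index_col=0))


@dataclass
class RhythmResult:
    """Per-feature outcome of the dual circadian test."""

    feature_id: str
    p_jtk: float
    p_umbrella: float
    best_lag_h: float
    tau_max: float
    is_circadian: bool
    peak_phase_h: float


def results_to_frame(results: list[RhythmResult]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in results]).set_index("feature_id")


@dataclass
class PhaseClustering:
    scaled_matrix: pd.DataFrame
    cluster_of: pd.Series
    k: int


# ---------------------------------------------------------------------------
# permutation engine
# ---------------------------------------------------------------------------

def _collect(values_by_timepoint) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Flatten a {ct: replicate values} mapping into (values, slots, cts)."""
    cts = np.asarray(sorted(values_by_timepoint), dtype=float)
    vals, slots = [], []
    for s, ct in enumerate(cts):
        arr = np.asarray(values_by_timepoint[ct], dtype=float).ravel()
        arr = arr[np.isfinite(arr)]
        vals.append(arr)
        slots.append(np.full(arr.size, s))
    v = np.concatenate(vals) if vals else np.array([])
    slots_arr = np.concatenate(slots) if slots else np.array([], dtype=int)
    present = {s for s in slots_arr}
    if len(present) < 2:
        raise ValueError("need at least two timepoints with at least one value each")
    return v, slots_arr.astype(int), cts


def _pairwise_less(v: np.ndarray) -> np.ndarray:
    """G[i, j] = 1 if v_i < v_j, 0.5 on off-diagonal ties, 0 otherwise."""
    diff = v[None, :] - v[:, None]
    g = (diff > 0).astype(float) + 0.5 * (diff == 0)
    np.fill_diagonal(g, 0.0)
    return g


def _jtk_matrices(cts, slots, lags_h, period_h):
    """Per-lag antisymmetric reference-sign matrices and tau denominators."""
    n = slots.size
    n0 = n * (n - 1) / 2.0
    s_mats, denom_r = [], []
    for lag in lags_h:
        # round so quarter-phase reference values tie exactly at 0
        r = np.round(np.cos(2 * np.pi * ((cts[slots] % 24.0) - lag) / period_h), 9)
        s_mats.append(np.sign(r[None, :] - r[:, None]))
        eq = r[None, :] == r[:, None]
        n2 = (eq.sum() - n) / 2.0
        denom_r.append(n0 - n2)
    return np.stack(s_mats), np.asarray(denom_r), n0


def _umbrella_matrices(cts, slots, candidate_peaks_h):
    """Per-candidate pair-orientation matrices W and their null means.

    For candidate peak k each folded phase (CT24 folds to CT0) is mapped to
    an umbrella height equal to minus its distance to k on the 24 h circle,
    so the implied trough sits at the antipodal phase — the shape of any
    cosine peaking at k.  W[i, j] = 1 for observation pairs whose heights
    strictly increase (the Mann-Whitney orientation of the rise to the peak
    and the fall after it).
    """
    folded = cts % 24.0
    w_mats, centers = [], []
    for k in candidate_peaks_h:
        d = np.abs(folded - k)
        h = -np.minimum(d, 24.0 - d)[slots]
        w = (h[:, None] < h[None, :]).astype(float)
        w_mats.append(w)
        centers.append(0.5 * w.sum())
    return np.stack(w_mats), np.asarray(centers)


def _n_arrangements(slots: np.ndarray) -> int:
    n = slots.size
    total = math.factorial(n)
    for _, cnt in zip(*np.unique(slots, return_counts=True)):
        total //= math.factorial(int(cnt))
    return total


def _iter_exhaustive_perms(slots: np.ndarray):
    """Yield one index permutation per distinct assignment of observations
    to slot groups (order within a group is irrelevant to both statistics)."""
    sizes = np.unique(slots, return_counts=True)[1]
    order = np.argsort(slots, kind="stable")  # canonical grouped layout

    def rec(remaining: tuple, sizes_left):
        if not sizes_left:
            yield ()
            return
        k = sizes_left[0]
        for comb in itertools.combinations(remaining, k):
            rest = tuple(i for i in remaining if i not in comb)
            for tail in rec(rest, sizes_left[1:]):
                yield comb + tail

    for assignment in rec(tuple(range(slots.size)), list(sizes)):
        perm = np.empty(slots.size, dtype=int)
        perm[order] = np.asarray(assignment)
        yield perm


def _stats_from_g(g, s_mats, denom_r, n0, n1, w_mats, centers):
    """(jtk_max_tau, jtk_argmax, umbrella_max, umbrella_argmax) from one G."""
    nums = np.tensordot(s_mats, g, axes=([1, 2], [0, 1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        taus = nums / np.sqrt((n0 - n1) * denom_r)
    taus = np.where(np.isfinite(taus), taus, 0.0)
    a = np.tensordot(w_mats, g, axes=([1, 2], [0, 1])) - centers
    return taus, a


class _PermutationNull:
    """Null distributions of both max statistics under slot permutation."""

    def __init__(self, jtk_max: np.ndarray, umbrella_max: np.ndarray, exhaustive: bool):
        self.jtk_max = jtk_max
        self.umbrella_max = umbrella_max
        self.exhaustive = exhaustive

    def p_value(self, which: str, observed: float) -> float:
        null = self.jtk_max if which == "jtk" else self.umbrella_max
        hits = int(np.sum(null >= observed - 1e-9))
        if self.exhaustive:
            return hits / null.size
        return (1 + hits) / (null.size + 1)


def _build_null(
    v, slots, s_mats, denom_r, n0, w_mats, centers,
    n_perms, rng, exhaustive_bound,
) -> _PermutationNull:
    n = v.size
    n1 = _tie_pairs(v)
    total = _n_arrangements(slots)
    if total <= exhaustive_bound:
        perms = np.array(list(_iter_exhaustive_perms(slots)))
        exhaustive = True
    else:
        perms = np.argsort(rng.random((n_perms, n)), axis=1)
        exhaustive = False

    g = _pairwise_less(v)
    jtk_null = np.empty(perms.shape[0])
    umb_null = np.empty(perms.shape[0])
    chunk = 2000
    for lo in range(0, perms.shape[0], chunk):
        pp = perms[lo : lo + chunk]
        gp = g[pp[:, :, None], pp[:, None, :]]
        nums = np.einsum("lij,bij->bl", s_mats, gp)
        with np.errstate(divide="ignore", invalid="ignore"):
            taus = nums / np.sqrt((n0 - n1) * denom_r)[None, :]
        taus = np.where(np.isfinite(taus), taus, 0.0)
        jtk_null[lo : lo + chunk] = taus.max(axis=1)
        a = np.einsum("kij,bij->bk", w_mats, gp) - centers[None, :]
        umb_null[lo : lo + chunk] = a.max(axis=1)
    return _PermutationNull(jtk_null, umb_null, exhaustive)


def _argmax_last(a: np.ndarray) -> int:
    """Index of the maximum, ties broken toward the last (latest) candidate.

    On a monotone trend every umbrella through the trailing phases ties; the
    boundary umbrella (peak at the last candidate) is reported."""
    return int(np.flatnonzero(a >= a.max() - 1e-9)[-1])


def _tie_pairs(v: np.ndarray) -> float:
    _, counts = np.unique(v, return_counts=True)
    return float(sum(c * (c - 1) / 2 for c in counts))


# ---------------------------------------------------------------------------
# the two tests
# ---------------------------------------------------------------------------

@dataclass
class JtkTestResult:
    tau_max: float
    best_lag_h: float
    p: float


@dataclass
class UmbrellaTestResult:
    p: float
    best_peak_h: float
    statistic: float


_DEFAULT_LAGS = (0.0, 6.0, 12.0, 18.0)


def jtk_test(
    values_by_timepoint,
    period_h: float = 24.0,
    lags_h=_DEFAULT_LAGS,
    n_perms: int = 10_000,
    seed: int | None = None,
    exhaustive_bound: int = 20_000,
) -> JtkTestResult:
    """Kendall-tau rhythmicity test against lagged cosine references.

    ``values_by_timepoint`` maps CT hours to replicate values.  CT24 is
    evaluated at CT mod 24 in the reference but its observations permute
    independently.  The p-value is the permutation tail probability of the
    max-over-lags tau (exhaustive when the number of distinct assignments is
    within ``exhaustive_bound``, Monte-Carlo with ``seed`` otherwise).
    """
    v, slots, cts = _collect(values_by_timepoint)
    if np.all(v == v[0]):
        return JtkTestResult(tau_max=0.0, best_lag_h=float("nan"), p=1.0)
    s_mats, denom_r, n0 = _jtk_matrices(cts, slots, lags_h, period_h)
    w_mats, centers = _umbrella_matrices(cts, slots, lags_h)
    n1 = _tie_pairs(v)
    taus, _ = _stats_from_g(_pairwise_less(v), s_mats, denom_r, n0, n1, w_mats, centers)
    best = int(np.argmax(taus))
    rng = np.random.default_rng(seed)
    null = _build_null(v, slots, s_mats, denom_r, n0, w_mats, centers,
                       n_perms, rng, exhaustive_bound)
    return JtkTestResult(
        tau_max=float(taus[best]),
        best_lag_h=float(lags_h[best]),
        p=null.p_value("jtk", float(taus[best])),
    )


def umbrella_test(
    values_by_timepoint,
    candidate_peaks_h=_DEFAULT_LAGS,
    n_perms: int = 10_000,
    seed: int | None = None,
    exhaustive_bound: int = 20_000,
) -> UmbrellaTestResult:
    """Umbrella-alternative trend test over candidate peak phases.

    For each candidate peak the statistic sums Mann-Whitney counts (ties at
    half weight) along the rise to the peak and the fall after it, centered
    at its permutation mean; the p-value is the permutation tail of the
    max-over-candidates statistic, sharing the engine and seed protocol of
    :func:`jtk_test`.
    """
    v, slots, cts = _collect(values_by_timepoint)
    if np.all(v == v[0]):
        return UmbrellaTestResult(p=1.0, best_peak_h=float("nan"), statistic=0.0)
    s_mats, denom_r, n0 = _jtk_matrices(cts, slots, candidate_peaks_h, 24.0)
    w_mats, centers = _umbrella_matrices(cts, slots, candidate_peaks_h)
    n1 = _tie_pairs(v)
    _, a = _stats_from_g(_pairwise_less(v), s_mats, denom_r, n0, n1, w_mats, centers)
    best = _argmax_last(a)
    rng = np.random.default_rng(seed)
    null = _build_null(v, slots, s_mats, denom_r, n0, w_mats, centers,
                       n_perms, rng, exhaustive_bound)
    return UmbrellaTestResult(
        p=null.p_value("umbrella", float(a[best])),
        best_peak_h=float(candidate_peaks_h[best]),
        statistic=float(a[best]),
    )


def call_circadian(
    table: OmicsTimeTable,
    alpha: float = 0.05,
    period_h: float = 24.0,
    lags_h=_DEFAULT_LAGS,
    candidate_peaks_h=_DEFAULT_LAGS,
    n_perms: int = 10_000,
    seed: int | None = None,
    exhaustive_bound: int = 20_000,
) -> list[RhythmResult]:
    """Run both tests on every feature and intersect the calls.

    A feature is circadian iff both permutation p-values fall below
    ``alpha`` (raw p-values, no across-feature correction).  The peak phase
    reported is the best cosine lag of the JTK-style test.  For complete,
    tie-free features the permutation null is shared across features, which
    makes the per-feature cost essentially one statistic evaluation.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    rng = np.random.default_rng(seed)
    null_cache: dict[tuple, _PermutationNull] = {}
    results = []
    for fid in table.feature_ids:
        vbt = table.values_by_timepoint(fid)
        try:
            v, slots, cts = _collect(vbt)
        except ValueError:
            results.append(RhythmResult(fid, 1.0, 1.0, float("nan"), 0.0, False,
                                        float("nan")))
            continue
        if np.all(v == v[0]):
            results.append(RhythmResult(fid, 1.0, 1.0, float("nan"), 0.0, False,
                                        float("nan")))
            continue
        s_mats, denom_r, n0 = _jtk_matrices(cts, slots, lags_h, period_h)
        w_mats, centers = _umbrella_matrices(cts, slots, candidate_peaks_h)
        n1 = _tie_pairs(v)
        g = _pairwise_less(v)
        taus, a = _stats_from_g(g, s_mats, denom_r, n0, n1, w_mats, centers)
        tie_free = n1 == 0
        key = (tuple(slots), tuple(cts[slots]), n_perms) if tie_free else None
        if key is not None and key in null_cache:
            null = null_cache[key]
        else:
            null = _build_null(v, slots, s_mats, denom_r, n0, w_mats, centers,
                               n_perms, rng, exhaustive_bound)
            if key is not None:
                null_cache[key] = null
        bj, bu = int(np.argmax(taus)), _argmax_last(a)
        p_j = null.p_value("jtk", float(taus[bj]))
        p_u = null.p_value("umbrella", float(a[bu]))
        circ = (p_j < alpha) and (p_u < alpha)
        results.append(
            RhythmResult(
                feature_id=fid,
                p_jtk=p_j,
                p_umbrella=p_u,
                best_lag_h=float(lags_h[bj]),
                tau_max=float(taus[bj]),
                is_circadian=bool(circ),
                peak_phase_h=float(lags_h[bj]),
            )
        )
    return results


# ---------------------------------------------------------------------------
# phase scaling, clustering, distribution, summary arithmetic
# ---------------------------------------------------------------------------

def scale_by_feature(matrix):
    """Min-max rescale each row to [0, 1]; constant rows map to 0.5."""
    df = pd.DataFrame(matrix)
    vals = df.to_numpy(dtype=float)
    lo = np.nanmin(vals, axis=1, keepdims=True)
    hi = np.nanmax(vals, axis=1, keepdims=True)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = (vals - lo) / span
    scaled = np.where(span == 0, 0.5, scaled)
    out = pd.DataFrame(scaled, index=df.index, columns=df.columns)
    return out if isinstance(matrix, pd.DataFrame) else out.to_numpy()


def phase_cluster(scaled_matrix, k: int = 4, seed: int = 0, n_init: int = 10) -> PhaseClustering:
    """K-means over per-feature-rescaled profiles, expecting one cluster per
    collection phase.  Clusters are renumbered 1..k by the timepoint of
    their centroid maximum so labels are reproducible across runs."""
    if k < 1:
        raise ValueError("k must be >= 1")
    df = pd.DataFrame(scaled_matrix)
    if k > len(df):
        raise ValueError("k exceeds the number of features")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(df.to_numpy())
    order = np.lexsort(
        (km.cluster_centers_.max(axis=1), np.argmax(km.cluster_centers_, axis=1))
    )
    relabel = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([relabel[c] for c in raw], index=df.index, name="cluster")
    return PhaseClustering(scaled_matrix=df, cluster_of=labels, k=k)


def phase_distribution(results: list[RhythmResult], bins=_DEFAULT_LAGS) -> dict[float, float]:
    """Fraction of circadian features peaking in each phase bin (sums to 1).

    CT24 peaks fold into the CT0 bin."""
    phases = [r.peak_phase_h % 24.0 for r in results if r.is_circadian]
    if not phases:
        raise ValueError("no circadian features")
    counts = {float(b): 0 for b in bins}
    for ph in phases:
        b = min(counts, key=lambda c: min(abs(ph - c), 24 - abs(ph - c)))
        counts[b] += 1
    total = len(phases)
    return {b: c / total for b, c in counts.items()}


def call_rate_summary(
    n_quantified: int,
    n_umbrella: int,
    n_jtk: int,
    n_both: int,
    n_identified: int | None = None,
) -> dict[str, float]:
    """Summary arithmetic of a dual-criterion circadian screen.

    Given the number of quantified features, single-test calls and the
    dual-call overlap, reports each call set as a percentage of the
    quantified proteome and the overlap as a percentage of each single-test
    call set.
    """
    if n_both > min(n_umbrella, n_jtk):
        raise ValueError("overlap cannot exceed either single-test call set")
    out = {
        "pct_umbrella_of_quantified": 100.0 * n_umbrella / n_quantified,
        "pct_jtk_of_quantified": 100.0 * n_jtk / n_quantified,
        "pct_circadian_of_quantified": 100.0 * n_both / n_quantified,
        "pct_overlap_of_umbrella": 100.0 * n_both / n_umbrella,
        "pct_overlap_of_jtk": 100.0 * n_both / n_jtk,
    }
    if n_identified is not None:
        out["pct_quantified_of_identified"] = 100.0 * n_quantified / n_identified
    return out
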