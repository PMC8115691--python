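"""Reconstruction of genome-wide background allelic dosage (BAD) maps.

BAD is the ratio of major to minor allele copy number in a genomic segment;
it sets the null read-count ratio against which allelic imbalance must be
judged.  The caller works from heterozygous SNV read counts alone (no
genomic input control): for each SNV the statistic is ``x = min(C_ref,
C_alt)`` with total coverage ``n = C_ref + C_alt``, and ``C_ref`` is modelled
as an equal-weight mixture of two binomials with success probabilities
``1/(BAD+1)`` and ``BAD/(BAD+1)`` (the two possible haplotype phasings),
truncated to ``5 <= k <= n-5`` to mirror the upstream per-allele read filter.

Segmentation is exact: changepoints between consecutive SNVs are chosen by
dynamic programming to maximise the sum of per-segment log marginal
likelihoods (BAD integrated out over a discrete grid with a uniform prior)
minus a per-changepoint penalty.  Each segment is then assigned the BAD with
maximal posterior.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from fractions import Fraction
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import logsumexp
from sklearn.metrics import auc, precision_recall_curve, roc_curve

#: admissible BAD values; total copy number of a locus rarely exceeds 7
DEFAULT_BAD_GRID = (1.0, 4 / 3, 3 / 2, 2.0, 5 / 2, 3.0, 4.0, 5.0, 6.0)

#: truncation bound mirroring the >=5-reads-per-allele variant filter
TRUNC = 5

#: sentinel for classifier scores of SNVs outside any segment
UNDEFINED_SCORE = float("nan")


@dataclass(frozen=True)
class BadGrid:
    """Discrete set of admissible BAD values with a prior over them."""

    values: tuple[float, ...] = DEFAULT_BAD_GRID
    prior: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if not vals or any(v <= 0 for v in vals):
            raise ValueError("BAD values must be positive")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise ValueError("BAD values must be strictly increasing")
        object.__setattr__(self, "values", vals)
        if self.prior is None:
            object.__setattr__(self, "prior", (1.0 / len(vals),) * len(vals))
        else:
            pr = tuple(float(p) for p in self.prior)
            if len(pr) != len(vals) or abs(sum(pr) - 1.0) > 1e-9:
                raise ValueError("prior must match grid and sum to 1")
            object.__setattr__(self, "prior", pr)

    @property
    def log_prior(self) -> np.ndarray:
        return np.log(np.asarray(self.prior))

    @classmethod
    def from_string(cls, text: str) -> "BadGrid":
        """Parse a comma-separated grid such as ``"1,4/3,3/2,2,3"``."""
        return cls(tuple(float(Fraction(tok)) for tok in text.split(",")))


@dataclass(frozen=True)
class SnvObservation:
    """Position plus the (min count, total coverage) summary of one SNV."""

    pos: int
    x: int
    n: int

    def __post_init__(self) -> None:
        if not (TRUNC <= self.x <= self.n - self.x):
            raise ValueError(
                f"observation (x={self.x}, n={self.n}) violates the "
                f"{TRUNC} <= x <= n - x coverage invariant")


def observations_from_calls(calls) -> list[SnvObservation]:
    """Summarise filtered SnvCalls as (pos, min count, coverage) tuples."""
    return [SnvObservation(c.pos, min(c.c_ref, c.c_alt), c.c_ref + c.c_alt)
            for c in calls]


def trunc_binom_log_likelihood(obs: SnvObservation | tuple, bad: float) -> float:
    """Log P(min(C_ref, C_alt) = x | n, BAD) under the truncated model.

    ``C_ref`` follows the equal-weight two-binomial haplotype mixture with
    p = 1/(BAD+1) and BAD/(BAD+1), truncated to ``TRUNC <= k <= n - TRUNC``
    and renormalised; P(min = x) = P(k = x) + P(k = n - x), the two terms
    coinciding when x = n - x.
    """
    if isinstance(obs, SnvObservation):
        x, n = obs.x, obs.n
    else:
        _, x, n = obs
    return float(_loglik_matrix(np.array([x]), np.array([n]), (float(bad),))[0, 0])


def _loglik_matrix(x: np.ndarray, n: np.ndarray,
                   grid_values: Sequence[float]) -> np.ndarray:
    """Per-observation, per-BAD truncated-mixture log-likelihoods.

    Both mixture components share the truncated normaliser (they are mirror
    images under k -> n - k), so the normaliser is computed once per
    observation from the p-component CDF.
    """
    x = np.asarray(x, dtype=int)
    n = np.asarray(n, dtype=int)
    if np.any(n < 2 * TRUNC):
        raise ValueError(f"total coverage below {2 * TRUNC}: truncated support empty")
    out = np.empty((len(x), len(grid_values)))
    for j, bad in enumerate(grid_values):
        p = 1.0 / (bad + 1.0)
        # mixture pmf g(k) = (f_p(k) + f_p(n-k)) / 2 is symmetric, so
        # P(min = x) = g(x) + g(n - x) = f_p(x) + f_p(n - x) for x < n - x
        lo = stats.binom.logpmf(x, n, p)
        hi = stats.binom.logpmf(n - x, n, p)
        num = np.where(x == n - x, lo, np.logaddexp(lo, hi))
        z = stats.binom.cdf(n - TRUNC, n, p) - stats.binom.cdf(TRUNC - 1, n, p)
        out[:, j] = num - np.log(z)
    return out


def expected_minor_fraction(bad: float, n: int) -> float:
    """E[min(C_ref, C_alt)] / n under the truncated mixture at coverage n."""
    xs = np.arange(TRUNC, n // 2 + 1)
    logp = _loglik_matrix(xs, np.full_like(xs, n), (float(bad),))[:, 0]
    return float(np.exp(logp) @ xs) / n


def expected_allele_ratio(bad: float, n: int = 500) -> float:
    """Expected major:minor read-count ratio at the given BAD.

    Computed from the truncated binomial haplotype component with success
    probability BAD/(BAD+1): the expected reads on the amplified haplotype
    divided by the expected reads on the other.  At BAD = 1 the components
    coincide and the ratio is exactly 1; at BAD = b and coverage large
    enough for truncation to be negligible it approaches b.
    """
    p = bad / (bad + 1.0)
    ks = np.arange(TRUNC, n - TRUNC + 1)
    w = stats.binom.pmf(ks, n, p)
    w /= w.sum()
    e_major = float(w @ ks)
    return e_major / (n - e_major)


# ---------------------------------------------------------------------------
# segmentation


@dataclass
class BadSegment:
    """A genomic interval of constant BAD (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    snv_count: int
    log_likelihood: np.ndarray  # summed log L(BAD=b) over SNVs, per grid value
    assigned_bad: float | None = None
    posterior: np.ndarray | None = None


@dataclass
class ExcludedInterval:
    """An interval removed from BAD calling (SNV-free gap or tiny region)."""

    chrom: str
    start: int
    end: int
    reason: str


def split_by_gaps(
    observations: Sequence[SnvObservation],
    chrom: str,
    gap_bp: int = 1_000_000,
    min_snvs: int = 3,
) -> tuple[list[list[SnvObservation]], list[ExcludedInterval]]:
    """Break a chromosome at long SNV-free gaps; drop tiny leftover regions.

    Gaps longer than ``gap_bp`` between neighbouring SNVs flag deletions,
    centromeres and other regions where BAD cannot be followed; regions left
    with fewer than ``min_snvs`` SNVs carry too little signal and are
    excluded.
    """
    obs = sorted(observations, key=lambda o: o.pos)
    regions: list[list[SnvObservation]] = []
    excluded: list[ExcludedInterval] = []
    if not obs:
        return regions, excluded
    current = [obs[0]]
    for prev, nxt in zip(obs, obs[1:]):
        if nxt.pos - prev.pos > gap_bp:
            regions.append(current)
            excluded.append(ExcludedInterval(chrom, prev.pos, nxt.pos - 1, "gap"))
            current = []
        current.append(nxt)
    regions.append(current)
    kept = []
    for region in regions:
        if len(region) < min_snvs:
            excluded.append(ExcludedInterval(
                chrom, region[0].pos - 1, region[-1].pos, "too_few_snvs"))
        else:
            kept.append(region)
    return kept, excluded


def _segment_boundaries(positions: Sequence[int], cuts: Sequence[int]) -> list[tuple[int, int]]:
    """Genomic (start, end) for segments split at observation indices ``cuts``.

    Interior boundaries sit at the midpoint between flanking SNVs; the
    outermost boundaries hug the first/last SNV (0-based half-open).
    """
    edges = [positions[0] - 1]
    for c in cuts:
        edges.append((positions[c - 1] + positions[c]) // 2)
    edges.append(positions[-1])
    return list(zip(edges[:-1], edges[1:]))


def segment_region(
    observations: Sequence[SnvObservation],
    grid: BadGrid = BadGrid(),
    changepoint_penalty: float = 10.0,
    chrom: str = "chr",
    min_seg_snvs: int = 3,
) -> list[BadSegment]:
    """Optimal changepoint placement by dynamic programming.

    Maximises ``sum_segments log ML(segment) - n_changepoints * penalty``,
    where a segment's marginal likelihood integrates BAD over the grid:
    ``ML = sum_b prior(b) * prod_i P_b(x_i)``.  Segments shorter than
    ``min_seg_snvs`` SNVs are disallowed; the optimum is global.
    """
    obs = sorted(observations, key=lambda o: o.pos)
    n = len(obs)
    if n == 0:
        raise ValueError("segment_region requires at least one observation")
    if n < min_seg_snvs:
        raise ValueError(f"need >= {min_seg_snvs} observations, got {n}")
    x = np.array([o.x for o in obs])
    tot = np.array([o.n for o in obs])
    ll = _loglik_matrix(x, tot, grid.values)          # (n, B)
    cum = np.vstack([np.zeros(len(grid.values)), np.cumsum(ll, axis=0)])
    log_prior = grid.log_prior

    # best[j]: optimal objective for the prefix of j observations
    best = np.full(n + 1, -np.inf)
    best[0] = 0.0
    back = np.zeros(n + 1, dtype=int)
    for j in range(min_seg_snvs, n + 1):
        starts = np.arange(0, j - min_seg_snvs + 1)
        seg_ll = logsumexp(log_prior[None, :] + cum[j] - cum[starts], axis=1)
        cand = best[starts] + seg_ll - np.where(starts > 0, changepoint_penalty, 0.0)
        k = int(np.argmax(cand))
        best[j] = cand[k]
        back[j] = starts[k]

    cuts: list[int] = []
    j = n
    while j > 0:
        i = back[j]
        if i > 0:
            cuts.append(i)
        j = i
    cuts.reverse()

    positions = [o.pos for o in obs]
    bounds = _segment_boundaries(positions, cuts)
    idx_edges = [0, *cuts, n]
    segments = []
    for (start, end), i, j in zip(bounds, idx_edges[:-1], idx_edges[1:]):
        seg = BadSegment(chrom=chrom, start=start, end=end, snv_count=j - i,
                         log_likelihood=cum[j] - cum[i])
        segments.append(assign_bad(seg, grid))
    return segments


def assign_bad(segment: BadSegment, grid: BadGrid = BadGrid()) -> BadSegment:
    """Assign the maximum-posterior BAD; ties break toward the smaller BAD."""
    logpost = grid.log_prior + segment.log_likelihood
    logpost = logpost - logsumexp(logpost)
    post = np.exp(logpost)
    segment.posterior = post / post.sum()
    # argmax returns the first maximum; the grid is ascending, so ties
    # resolve to the smaller BAD (parsimony: fewer implied copies)
    segment.assigned_bad = grid.values[int(np.argmax(post))]
    return segment


# ---------------------------------------------------------------------------
# model / results objects


class BadCaller:
    """Model object: grouped SNV observations ready for BAD segmentation.

    Parameters
    ----------
    observations : mapping of chromosome name to SnvObservation sequences
    grid : admissible BAD values and their prior
    gap_bp : SNV-free gap length that splits a chromosome (default 1 Mb)
    changepoint_penalty : per-changepoint log-likelihood penalty; the default
        is calibrated so that homogeneous diploid regions of ~1000 SNVs are
        split spuriously in fewer than 5% of replicates
    """

    def __init__(
        self,
        observations: Mapping[str, Sequence[SnvObservation]],
        grid: BadGrid = BadGrid(),
        gap_bp: int = 1_000_000,
        changepoint_penalty: float = 10.0,
        min_snvs_per_region: int = 3,
    ) -> None:
        self.observations = {c: sorted(o, key=lambda s: s.pos)
                             for c, o in observations.items()}
        self.grid = grid
        self.gap_bp = int(gap_bp)
        self.changepoint_penalty = float(changepoint_penalty)
        self.min_snvs_per_region = int(min_snvs_per_region)

    @classmethod
    def from_calls(cls, calls, **kwargs) -> "BadCaller":
        by_chrom: dict[str, list[SnvObservation]] = {}
        for c in calls:
            by_chrom.setdefault(c.chrom, []).append(
                SnvObservation(c.pos, min(c.c_ref, c.c_alt), c.c_ref + c.c_alt))
        return cls(by_chrom, **kwargs)

    def fit(self) -> "BadMap":
        segments: list[BadSegment] = []
        excluded: list[ExcludedInterval] = []
        for chrom in sorted(self.observations):
            regions, excl = split_by_gaps(
                self.observations[chrom], chrom, self.gap_bp,
                self.min_snvs_per_region)
            excluded.extend(excl)
            for region in regions:
                segments.extend(segment_region(
                    region, self.grid, self.changepoint_penalty, chrom,
                    self.min_snvs_per_region))
        return BadMap(segments, excluded, self.grid)


class BadMap:
    """Results object: the genome-wide piecewise-constant BAD map."""

    def __init__(self, segments: Sequence[BadSegment],
                 excluded: Sequence[ExcludedInterval] = (),
                 grid: BadGrid = BadGrid()) -> None:
        self.segments = sorted(segments, key=lambda s: (s.chrom, s.start))
        self.excluded = list(excluded)
        self.grid = grid
        self._starts: dict[str, list[int]] = {}
        self._by_chrom: dict[str, list[BadSegment]] = {}
        for seg in self.segments:
            self._by_chrom.setdefault(seg.chrom, []).append(seg)
        for chrom, segs in self._by_chrom.items():
            prev_end = None
            for s in segs:
                if prev_end is not None and s.start < prev_end:
                    raise ValueError(f"overlapping segments on {chrom}")
                prev_end = s.end
            self._starts[chrom] = [s.start for s in segs]

    def segment_at(self, chrom: str, pos: int) -> BadSegment | None:
        """Segment containing the 1-based position ``pos``, if any."""
        segs = self._by_chrom.get(chrom)
        if not segs:
            return None
        i = bisect.bisect_right(self._starts[chrom], pos - 1) - 1
        if i >= 0 and segs[i].start <= pos - 1 < segs[i].end:
            return segs[i]
        return None

    def bad_at(self, chrom: str, pos: int) -> float | None:
        seg = self.segment_at(chrom, pos)
        return None if seg is None else seg.assigned_bad

    def classifier_score(self, chrom: str, pos: int, bad: float) -> float:
        """S = L(BAD = bad) - max over other BADs of L; NaN outside the map.

        Under the uniform prior, S > 0 exactly when the segment's assigned
        BAD equals the queried one.
        """
        seg = self.segment_at(chrom, pos)
        if seg is None:
            return UNDEFINED_SCORE
        values = np.asarray(self.grid.values)
        j = int(np.argmin(np.abs(values - bad)))
        if not np.isclose(values[j], bad):
            raise ValueError(f"BAD {bad} not on the grid")
        others = np.delete(seg.log_likelihood, j)
        return float(seg.log_likelihood[j] - others.max())

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.segments:
            row = {"chrom": s.chrom, "start": s.start, "end": s.end,
                   "bad": s.assigned_bad, "snv_count": s.snv_count}
            for v, ll in zip(self.grid.values, s.log_likelihood):
                row[f"L_{v:g}"] = ll
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.to_frame()
        lines = ["BAD map summary",
                 f"  segments: {len(self.segments)}",
                 f"  excluded intervals: {len(self.excluded)}"]
        if len(df):
            counts = df.groupby("bad")["snv_count"].agg(["count", "sum"])
            lines.append("  BAD  segments  SNVs")
            for bad, row in counts.iterrows():
                lines.append(f"  {bad:>4g}  {int(row['count']):>8d}  {int(row['sum']):>5d}")
        return "\n".join(lines)

    def evaluate(self, truth: "BadMap | Sequence[tuple]", snvs) -> dict:
        return evaluate_map(self, truth, snvs)


def _truth_lookup(truth) -> "BadMap":
    if isinstance(truth, BadMap):
        return truth
    segs = [BadSegment(chrom=c, start=int(s), end=int(e), snv_count=0,
                       log_likelihood=np.zeros(1), assigned_bad=float(b))
            for c, s, e, b in truth]
    return BadMap(segs, grid=BadGrid((1.0,)))


def evaluate_map(badmap: BadMap, truth, snvs) -> dict:
    """SNV-level agreement between a predicted map and ground-truth markup.

    ``truth`` is a BadMap or an iterable of (chrom, start, end, bad)
    intervals (0-based half-open).  Only SNVs falling into regions of known
    BAD are considered, recurrent SNVs are counted once.  Returns Kendall's
    tau-b over paired (predicted, true) BADs, overall accuracy, and one-vs-
    rest ROC / precision-recall curves per BAD built by thresholding the
    classifier score.
    """
    truth_map = _truth_lookup(truth)
    seen = set()
    pred, true, keys = [], [], []
    for snv in snvs:
        chrom, pos = (snv.chrom, snv.pos) if hasattr(snv, "chrom") else snv[:2]
        if (chrom, pos) in seen:
            continue
        seen.add((chrom, pos))
        t = truth_map.bad_at(chrom, pos)
        p = badmap.bad_at(chrom, pos)
        if t is None or p is None:
            continue
        pred.append(p)
        true.append(t)
        keys.append((chrom, pos))
    if not pred:
        raise ValueError("no SNVs overlap the ground-truth markup")
    pred_arr = np.asarray(pred)
    true_arr = np.asarray(true)
    tau = stats.kendalltau(pred_arr, true_arr, variant="b")
    metrics = {
        "n_snvs": len(pred),
        "kendall_tau_b": float(tau.statistic) if len(set(true)) > 1 else np.nan,
        "accuracy": float(np.mean(np.isclose(pred_arr, true_arr))),
        "per_bad": {},
    }
    for bad in sorted(set(true)):
        labels = np.isclose(true_arr, bad).astype(int)
        if labels.all() or not labels.any():
            continue
        scores = np.array([badmap.classifier_score(c, p, bad) for c, p in keys])
        ok = np.isfinite(scores)
        fpr, tpr, _ = roc_curve(labels[ok], scores[ok])
        prec, rec, _ = precision_recall_curve(labels[ok], scores[ok])
        metrics["per_bad"][bad] = {
            "roc": (fpr, tpr),
            "prc": (prec, rec),
            "auroc": float(auc(fpr, tpr)),
            "auprc": float(auc(rec, prec)),
        }
    return metrics
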