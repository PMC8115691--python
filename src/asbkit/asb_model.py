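"""Truncated negative-binomial mixture background for ASB scoring.

For every combination of BAD, fixed allele (ref or alt) and fixed read count
``m`` on that allele, the read count on the *other* allele across all SNVs
sharing that combination is modelled as a two-component negative-binomial
mixture::

    X | m  ~  (1 - w) NB(r, p) + w NB(r, 1 - p),      p = 1 / (BAD + 1)

where NB(r, p) counts successes before ``r`` failures with per-trial success
probability ``p``, truncated to ``X >= 5`` (the per-allele read filter) via
the normaliser ``A = 1 - P(X < 5)``.  ``p`` is fixed by the BAD; only ``r``
and ``w`` are fitted (L-BFGS-B from ``r = m``, ``w = 0.5``).  Fitting ``r``
freely (rather than pinning it to ``m``) absorbs reference-mapping bias:
fits for reference-allele counts come out with systematically larger ``r``
than fits for alternative-allele counts at the same ``m``.

Fits are gated by the RMSEA goodness-of-fit index; poor fits fall back to
the conservative parameter-free null ``r = m``, ``w = 1`` (the component
whose mean is ``m * BAD``), which penalises ASB significance.

One-tailed P values, ``P(X >= c | X >= 5)``, are computed independently for
the reference and alternative allele; effect sizes are
``log2(observed / E[X | X >= 5])``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

#: truncation bound, mirroring the variant-level per-allele read filter
TRUNC = 5

#: RMSEA above which a fit is discarded in favour of the fallback
RMSEA_GATE = 0.05

DEFAULT_MAX_M = 200
DEFAULT_MIN_OBS = 50


def _components(r: float, p: float):
    """The two scipy frozen NB components for paper-style NB(r, p) and NB(r, 1-p).

    scipy's nbinom(n, q) has pmf C(k+n-1, k) q^n (1-q)^k, i.e. per-trial
    *failure* probability q; the component with success probability p is
    therefore nbinom(r, 1 - p).
    """
    return stats.nbinom(r, 1.0 - p), stats.nbinom(r, p)


@dataclass
class NbMixtureFit:
    """Fitted (or fallback) mixture for one (BAD, fixed allele, m) cell.

    ``status`` is "fitted" when the likelihood optimisation succeeded and
    passed the RMSEA gate, "fallback" otherwise (then ``r = m``, ``w = 1``).
    """

    bad: float
    fixed_allele: str  # which allele's count is conditioned on: "ref" or "alt"
    m: int
    r: float
    w: float
    rmsea: float | None = None
    status: str = "fitted"
    n_obs: int = 0

    def __post_init__(self) -> None:
        if self.r <= 0:
            raise ValueError("r must be positive")
        if not 0.0 <= self.w <= 1.0:
            raise ValueError("w must lie in [0, 1]")
        if self.fixed_allele not in ("ref", "alt"):
            raise ValueError("fixed_allele must be 'ref' or 'alt'")

    @classmethod
    def fallback(cls, bad: float, fixed_allele: str, m: int,
                 n_obs: int = 0, rmsea: float | None = None) -> "NbMixtureFit":
        return cls(bad=bad, fixed_allele=fixed_allele, m=m, r=float(m), w=1.0,
                   rmsea=rmsea, status="fallback", n_obs=n_obs)

    # -- distribution interface -------------------------------------------

    @property
    def p(self) -> float:
        return 1.0 / (self.bad + 1.0)

    @property
    def trunc_norm(self) -> float:
        """A = 1 - P(X < 5) of the untruncated mixture."""
        cached = self.__dict__.get("_trunc_norm")
        if cached is None:
            c1, c2 = _components(self.r, self.p)
            cached = float((1.0 - self.w) * c1.sf(TRUNC - 1)
                           + self.w * c2.sf(TRUNC - 1))
            self.__dict__["_trunc_norm"] = cached
        return cached

    def pmf(self, x) -> np.ndarray | float:
        """Truncated mixture pmf at x (x >= 5)."""
        x = np.asarray(x)
        c1, c2 = _components(self.r, self.p)
        raw = (1.0 - self.w) * c1.pmf(x) + self.w * c2.pmf(x)
        out = np.where(x >= TRUNC, raw / self.trunc_norm, 0.0)
        return float(out) if out.ndim == 0 else out

    def logpmf(self, x) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        c1, c2 = _components(self.r, self.p)
        terms = []
        if self.w < 1.0:
            terms.append(np.log1p(-self.w) + c1.logpmf(x))
        if self.w > 0.0:
            terms.append(np.log(self.w) + c2.logpmf(x))
        num = terms[0] if len(terms) == 1 else np.logaddexp(*terms)
        out = np.where(x >= TRUNC, num - math.log(self.trunc_norm), -np.inf)
        return float(out) if out.ndim == 0 else out

    def sf_trunc(self, x) -> np.ndarray | float:
        """Upper tail P(X >= x | X >= 5); equals 1 for any x <= 5."""
        x = np.asarray(x)
        c1, c2 = _components(self.r, self.p)
        upper = (1.0 - self.w) * c1.sf(x - 1) + self.w * c2.sf(x - 1)
        out = np.clip(np.where(x <= TRUNC, 1.0, upper / self.trunc_norm), 0.0, 1.0)
        return float(out) if out.ndim == 0 else out

    def expectation_trunc(self) -> float:
        """E[X | X >= 5] under the fitted mixture."""
        cached = self.__dict__.get("_expectation_trunc")
        if cached is None:
            c1, c2 = _components(self.r, self.p)
            mean_full = (1.0 - self.w) * c1.mean() + self.w * c2.mean()
            ks = np.arange(TRUNC)
            below = float(ks @ ((1.0 - self.w) * c1.pmf(ks) + self.w * c2.pmf(ks)))
            cached = (mean_full - below) / self.trunc_norm
            self.__dict__["_expectation_trunc"] = cached
        return cached

    def summary(self) -> str:
        rm = "NA" if self.rmsea is None else f"{self.rmsea:.4f}"
        return (f"NB mixture fit [{self.status}]  BAD={self.bad:g}  "
                f"fixed {self.fixed_allele} m={self.m}  r={self.r:.3f}  "
                f"w={self.w:.3f}  RMSEA={rm}  n={self.n_obs}")


def mixture_pmf(x: int, fit: NbMixtureFit) -> float:
    """Probability of ``x`` reads on the scored allele under the cell's fit."""
    if x < TRUNC:
        raise ValueError(f"x must be >= {TRUNC} (truncated support)")
    return float(fit.pmf(x))


def rmsea(observed: Mapping[int, int] | Sequence[int], fit: NbMixtureFit) -> float | None:
    """Root mean square error of approximation of a fit to a count histogram.

    The chi-square statistic is computed over count bins pooled from the
    right so that every bin has expected mass >= 5; the rightmost bin absorbs
    the infinite tail.  Degrees of freedom are bins - 1 - 2 (two fitted
    parameters); RMSEA = sqrt(max(0, chi2/df - 1) / (N - 1)).  Returns None
    (undefined) when df <= 0, which triggers the fallback upstream.
    """
    if isinstance(observed, Mapping):
        hist = dict(observed)
    else:
        vals, cnts = np.unique(np.asarray(observed, dtype=int), return_counts=True)
        hist = dict(zip(vals.tolist(), cnts.tolist()))
    n_total = sum(hist.values())
    if n_total < 2:
        return None
    hi = max(hist)
    xs = np.arange(TRUNC, hi + 1)
    probs = fit.pmf(xs)
    obs = np.array([hist.get(int(v), 0) for v in xs], dtype=float)
    # tail beyond the largest observed count goes into a final bin
    tail = max(0.0, 1.0 - float(probs.sum()))
    exp = np.append(probs, tail) * n_total
    obs = np.append(obs, 0.0)

    # pool right-to-left until every bin expects >= 5 counts
    pooled_obs: list[float] = []
    pooled_exp: list[float] = []
    acc_o = acc_e = 0.0
    for o, e in zip(obs[::-1], exp[::-1]):
        acc_o += o
        acc_e += e
        if acc_e >= 5.0:
            pooled_obs.append(acc_o)
            pooled_exp.append(acc_e)
            acc_o = acc_e = 0.0
    if acc_e > 0 and pooled_exp:
        pooled_obs[-1] += acc_o
        pooled_exp[-1] += acc_e
    n_bins = len(pooled_exp)
    df = n_bins - 1 - 2
    if df <= 0:
        return None
    po = np.asarray(pooled_obs)
    pe = np.asarray(pooled_exp)
    chi2 = float(((po - pe) ** 2 / pe).sum())
    return math.sqrt(max(0.0, chi2 / df - 1.0) / (n_total - 1))


class NegBinMixtureModel:
    """Model object for one (BAD, fixed allele, m) cell.

    Parameters
    ----------
    counts : read counts on the scored allele, one per SNV, all >= 5
    bad : background allelic dosage of the SNVs in the cell
    m : fixed read count on the conditioning allele
    fixed_allele : "ref" or "alt" — which allele is conditioned on
    """

    def __init__(self, counts: Sequence[int], bad: float, m: int,
                 fixed_allele: str = "alt") -> None:
        counts = np.asarray(counts, dtype=int)
        if len(counts) and counts.min() < TRUNC:
            raise ValueError(f"all counts must be >= {TRUNC}")
        self.counts = counts
        self.bad = float(bad)
        self.m = int(m)
        self.fixed_allele = fixed_allele

    def _nll(self, params: np.ndarray, vals: np.ndarray, weights: np.ndarray) -> float:
        r, w = params
        fit = NbMixtureFit(self.bad, self.fixed_allele, self.m,
                           r=max(r, 1e-9), w=min(max(w, 0.0), 1.0),
                           n_obs=len(self.counts))
        ll = fit.logpmf(vals)
        if not np.all(np.isfinite(ll)):
            return 1e12
        return -float(weights @ ll)

    def fit(self, min_obs: int = DEFAULT_MIN_OBS,
            rmsea_gate: float = RMSEA_GATE) -> NbMixtureFit:
        """Maximise the truncated-mixture likelihood; gate by RMSEA.

        Falls back to ``r = m, w = 1`` when the cell is too small, the
        optimiser fails, or RMSEA exceeds the gate (or is undefined).
        """
        n = len(self.counts)
        if n < min_obs:
            return NbMixtureFit.fallback(self.bad, self.fixed_allele, self.m, n_obs=n)
        vals, cnts = np.unique(self.counts, return_counts=True)
        weights = cnts.astype(float)
        res = optimize.minimize(
            self._nll, x0=np.array([float(self.m), 0.5]),
            args=(vals.astype(float), weights),
            method="L-BFGS-B", bounds=[(1e-6, None), (0.0, 1.0)])
        if not res.success or not np.isfinite(res.fun):
            return NbMixtureFit.fallback(self.bad, self.fixed_allele, self.m, n_obs=n)
        r_hat, w_hat = float(res.x[0]), float(min(max(res.x[1], 0.0), 1.0))
        fit = NbMixtureFit(self.bad, self.fixed_allele, self.m, r=r_hat,
                           w=w_hat, status="fitted", n_obs=n)
        gof = rmsea(dict(zip(vals.tolist(), cnts.tolist())), fit)
        fit.rmsea = gof
        if gof is None or gof > rmsea_gate:
            return NbMixtureFit.fallback(self.bad, self.fixed_allele, self.m,
                                         n_obs=n, rmsea=gof)
        return fit


def fit_cell(observations: Sequence[int], bad: float, m: int,
             fixed_allele: str = "alt", min_obs: int = DEFAULT_MIN_OBS) -> NbMixtureFit:
    """Functional wrapper around :class:`NegBinMixtureModel`."""
    return NegBinMixtureModel(observations, bad, m, fixed_allele).fit(min_obs=min_obs)


class FitTable:
    """Collection of cell fits keyed by (BAD, fixed allele, m).

    Missing cells resolve to the fallback fit constructed on the fly, so
    P values and effect sizes are always defined.
    """

    def __init__(self, fits: Iterable[NbMixtureFit] = ()) -> None:
        self._fits: dict[tuple[float, str, int], NbMixtureFit] = {}
        for f in fits:
            self.add(f)

    def add(self, fit: NbMixtureFit) -> None:
        self._fits[(round(fit.bad, 6), fit.fixed_allele, fit.m)] = fit

    def get(self, bad: float, fixed_allele: str, m: int) -> NbMixtureFit:
        key = (round(float(bad), 6), fixed_allele, int(m))
        fit = self._fits.get(key)
        if fit is None:
            fit = NbMixtureFit.fallback(float(bad), fixed_allele, int(m))
            self._fits[key] = fit
        return fit

    def __len__(self) -> int:
        return len(self._fits)

    def __iter__(self):
        return iter(self._fits.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [{"bad": f.bad, "fixed_allele": f.fixed_allele, "m": f.m,
                 "r": f.r, "w": f.w,
                 "rmsea": np.nan if f.rmsea is None else f.rmsea,
                 "status": f.status, "n_obs": f.n_obs}
                for f in sorted(self, key=lambda f: (f.bad, f.fixed_allele, f.m))]
        return pd.DataFrame(rows, columns=["bad", "fixed_allele", "m", "r", "w",
                                           "rmsea", "status", "n_obs"])

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FitTable":
        fits = [NbMixtureFit(
            bad=float(r.bad), fixed_allele=str(r.fixed_allele), m=int(r.m),
            r=float(r.r), w=float(r.w),
            rmsea=None if pd.isna(r.rmsea) else float(r.rmsea),
            status=str(r.status), n_obs=int(r.n_obs)) for r in df.itertuples()]
        return cls(fits)

    @classmethod
    def fit_all(cls, cells: Mapping[tuple[float, str, int], Sequence[int]],
                max_m: int = DEFAULT_MAX_M,
                min_obs: int = DEFAULT_MIN_OBS) -> "FitTable":
        """Fit every populated cell with m <= max_m; larger m falls back."""
        table = cls()
        for (bad, allele, m), counts in cells.items():
            if m > max_m:
                table.add(NbMixtureFit.fallback(bad, allele, m, n_obs=len(counts)))
            else:
                table.add(fit_cell(counts, bad, m, allele, min_obs=min_obs))
        return table


def collect_cells(calls, badmap) -> dict[tuple[float, str, int], list[int]]:
    """Group scored-allele counts by (BAD, fixed allele, fixed count).

    The cell fixing the *alt* count models the distribution of reference
    reads (used for Ref-ASB scoring) and vice versa.  Calls outside the BAD
    map are skipped.
    """
    cells: dict[tuple[float, str, int], list[int]] = {}
    for c in calls:
        bad = badmap.bad_at(c.chrom, c.pos) if badmap is not None else 1.0
        if bad is None:
            continue
        cells.setdefault((bad, "alt", c.c_alt), []).append(c.c_ref)
        cells.setdefault((bad, "ref", c.c_ref), []).append(c.c_alt)
    return cells


def asb_pvalues(snv, bad: float, fits: FitTable) -> tuple[float, float]:
    """One-tailed P values for reference- and alternative-allele imbalance.

    p_ref = P(X >= c_ref | X >= 5) under the fit conditioning on the alt
    count; p_alt mirrors it with the roles of the alleles swapped.
    """
    fit_ref = fits.get(bad, "alt", snv.c_alt)
    fit_alt = fits.get(bad, "ref", snv.c_ref)
    return float(fit_ref.sf_trunc(snv.c_ref)), float(fit_alt.sf_trunc(snv.c_alt))


def effect_size(snv, bad: float, fits: FitTable) -> tuple[float, float]:
    """log2 observed/expected reads per allele under the background fits."""
    fit_ref = fits.get(bad, "alt", snv.c_alt)
    fit_alt = fits.get(bad, "ref", snv.c_ref)
    es_ref = math.log2(snv.c_ref / fit_ref.expectation_trunc())
    es_alt = math.log2(snv.c_alt / fit_alt.expectation_trunc())
    return es_ref, es_alt


def score_calls(calls, badmap, fits: FitTable) -> pd.DataFrame:
    """Per-dataset ASB scores for every call covered by the BAD map.

    P values and effect sizes are computed cell-by-cell (all calls sharing a
    (BAD, fixed allele, m) fit are scored in one vectorised pass).
    """
    kept = []
    bads = []
    for c in calls:
        bad = badmap.bad_at(c.chrom, c.pos) if badmap is not None else 1.0
        if bad is None:
            continue
        kept.append(c)
        bads.append(bad)
    if not kept:
        return pd.DataFrame(columns=_SCORE_COLUMNS)
    n = len(kept)
    p_ref = np.empty(n)
    p_alt = np.empty(n)
    es_ref = np.empty(n)
    es_alt = np.empty(n)
    by_cell: dict[tuple, list[int]] = {}
    for i, (c, bad) in enumerate(zip(kept, bads)):
        by_cell.setdefault((bad, "alt", c.c_alt), []).append(i)   # scores ref
        by_cell.setdefault((bad, "ref", c.c_ref), []).append(~i)  # scores alt
    for (bad, allele, m), idx in by_cell.items():
        fit = fits.get(bad, allele, m)
        expect = fit.expectation_trunc()
        ref_idx = np.array([i for i in idx if i >= 0], dtype=int)
        alt_idx = np.array([~i for i in idx if i < 0], dtype=int)
        if len(ref_idx):
            counts = np.array([kept[i].c_ref for i in ref_idx])
            p_ref[ref_idx] = fit.sf_trunc(counts)
            es_ref[ref_idx] = np.log2(counts / expect)
        if len(alt_idx):
            counts = np.array([kept[i].c_alt for i in alt_idx])
            p_alt[alt_idx] = fit.sf_trunc(counts)
            es_alt[alt_idx] = np.log2(counts / expect)
    rows = [{
        "chrom": c.chrom, "pos": c.pos, "ref_allele": c.ref_allele,
        "alt_allele": c.alt_allele, "snp_id": c.snp_id,
        "dataset_id": c.dataset_id, "c_ref": c.c_ref, "c_alt": c.c_alt,
        "bad": bad, "p_ref": p_ref[i], "p_alt": p_alt[i],
        "es_ref": es_ref[i], "es_alt": es_alt[i],
    } for i, (c, bad) in enumerate(zip(kept, bads))]
    return pd.DataFrame(rows, columns=_SCORE_COLUMNS)


_SCORE_COLUMNS = [
    "chrom", "pos", "ref_allele", "alt_allele", "snp_id", "dataset_id",
    "c_ref", "c_alt", "bad", "p_ref", "p_alt", "es_ref", "es_alt"]
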