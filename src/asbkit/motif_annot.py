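"""Motif annotation of ASBs: PWM hits, exact hit P values, concordance.

A position weight matrix (PWM) assigns each window a score that is additive
over positions.  The P value of a score is the probability that a random
background sequence of motif length scores at least as high; it is computed
exactly by dynamic programming over the discretised score distribution
(position-wise convolution), the same construction used by exact motif-scan
tools.

For each ASB SNP, every window overlapping the SNP is scored on both strands
for both alleles; the top-scoring hit (by the better allele) fixes one
window, and the motif fold change ``FC = log2(pval_ref / pval_alt)`` is
evaluated there — positive FC means the alternative allele has the stronger
(smaller-P) hit.  An ASB is motif-*concordant* when the allele it prefers
(the smaller ASB FDR) is also the allele with the stronger motif hit, and
*discordant* when it is the opposite one; SNPs without a significant hit or
with weak evidence fall into ``no_hit`` / ``weak``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

ALPHABET = "ACGT"
_INDEX = {c: i for i, c in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: motif-hit P value threshold defining a binding-site overlap
HIT_PVALUE = 0.0005
#: |log2 fold change| below which the allelic difference is called weak
FC_THRESHOLD = 2.0
#: ASB FDR threshold entering the concordance call
FDR_THRESHOLD = 0.05

#: default discretisation step of the score distribution, in score units
SCORE_STEP = 1e-3


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Pwm:
    """Log-odds position weight matrix (rows = positions, columns = ACGT)."""

    name: str
    matrix: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    step: float = SCORE_STEP

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4 or not len(self.matrix):
            raise ValueError("PWM matrix must be (length >= 1) x 4")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("PWM weights must be finite")
        self.background = np.asarray(self.background, dtype=float)
        if self.background.shape != (4,) or abs(self.background.sum() - 1) > 1e-6:
            raise ValueError("background must be 4 probabilities summing to 1")
        # quantised integer weights; all scoring happens on this grid so that
        # the score distribution and window scores are mutually consistent
        self._iw = np.rint(self.matrix / self.step).astype(np.int64)
        self._tail: np.ndarray | None = None
        self._offset: int = 0

    def __len__(self) -> int:
        return len(self.matrix)

    def score(self, seq: str) -> float:
        """Additive score of a window of motif length (quantised grid)."""
        if len(seq) != len(self):
            raise ValueError("sequence length must equal motif length")
        idx = [_INDEX[c] for c in seq.upper()]
        return float(self._iw[np.arange(len(self)), idx].sum() * self.step)

    # -- exact score distribution ------------------------------------------

    def _distribution(self) -> tuple[np.ndarray, int]:
        """Tail probabilities of the integer score distribution.

        Returns (tail, offset): tail[i] = P(S >= (i + offset) * step) for a
        random background sequence, computed by convolving one position at a
        time.
        """
        if self._tail is not None:
            return self._tail, self._offset
        # dist over current partial sums, index 0 <-> value cur_lo
        dist = np.array([1.0])
        cur_lo = 0
        for row in self._iw:
            new_lo = cur_lo + int(row.min())
            new_hi = cur_lo + len(dist) - 1 + int(row.max())
            new = np.zeros(new_hi - new_lo + 1)
            for letter, w in enumerate(row):
                shift = cur_lo + int(w) - new_lo
                new[shift:shift + len(dist)] += self.background[letter] * dist
            dist, cur_lo = new, new_lo
        tail = dist[::-1].cumsum()[::-1]
        self._tail, self._offset = tail, cur_lo
        return tail, cur_lo


def pwm_score_pvalue(pwm: Pwm, score: float) -> float:
    """P(random background window scores >= score), exact on the score grid."""
    tail, offset = pwm._distribution()
    # nudge guards against float noise when `score` came from Pwm.score
    i = math.ceil(score / pwm.step - 1e-6) - offset
    if i <= 0:
        return 1.0
    if i >= len(tail):
        return 0.0
    return float(tail[i])


def read_pwm(path: str | Path, background: Sequence[float] | None = None) -> Pwm:
    """Read a HOCOMOCO-style plain-text matrix (one row per position, ACGT).

    A leading ``>name`` header is honoured; otherwise the file stem names
    the motif.  Matrices with any negative entry are taken as log-odds
    weights as-is; non-negative matrices are treated as counts or
    probabilities and converted to log-odds against the background with a
    pseudo-weight of one count.
    """
    path = Path(path)
    name = path.stem
    rows = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            name = line[1:].split()[0]
            continue
        rows.append([float(tok) for tok in line.split()])
    matrix = np.asarray(rows, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if matrix.size and matrix.min() >= 0:
        totals = matrix.sum(axis=1, keepdims=True)
        freq = (matrix + bg) / (totals + 1.0)
        matrix = np.log(freq / bg)
    return Pwm(name=name, matrix=matrix, background=bg)


def write_pwm(pwm: Pwm, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{pwm.name}\n")
        for row in pwm.matrix:
            fh.write("\t".join(f"{v:.6f}" for v in row) + "\n")


@dataclass
class MotifHit:
    offset: int          # window start relative to the SNV position
    strand: str          # "+" or "-"
    score_ref: float
    score_alt: float


def best_hit(pwm: Pwm, context: str, snv_offset: int,
             ref_allele: str, alt_allele: str) -> MotifHit:
    """Top-scoring window over both alleles and strands.

    ``context`` is the genomic sequence around the SNV with the SNV base at
    ``snv_offset`` (its identity there is ignored; both alleles are
    substituted in turn).  All motif-length windows covering the SNV are
    scored on both strands for both alleles; the window maximising the
    better allele score is returned with both allele scores at that fixed
    window.  Ties prefer the forward strand, then the leftmost window.
    """
    L = len(pwm)
    context = context.upper()
    if snv_offset - (L - 1) < 0 or snv_offset + L > len(context):
        raise ValueError("context must cover motif-length-1 flanks of the SNV")
    best: MotifHit | None = None
    best_key: tuple | None = None
    for rel in range(-(L - 1), 1):
        start = snv_offset + rel
        window = context[start:start + L]
        scores = {}
        snv_in_window = snv_offset - start
        for allele_name, allele in (("ref", ref_allele), ("alt", alt_allele)):
            w = window[:snv_in_window] + allele + window[snv_in_window + 1:]
            scores[allele_name] = {
                "+": pwm.score(w),
                "-": pwm.score(reverse_complement(w)),
            }
        for strand in "+-":
            s_ref = scores["ref"][strand]
            s_alt = scores["alt"][strand]
            # larger best-allele score wins; '+' beats '-'; leftmost wins
            key = (max(s_ref, s_alt), strand == "+", -rel)
            if best_key is None or key > best_key:
                best_key = key
                best = MotifHit(offset=rel, strand=strand,
                                score_ref=s_ref, score_alt=s_alt)
    assert best is not None
    return best


def classify_concordance(fc: float | None, pval_ref: float, pval_alt: float,
                         fdr_ref: float, fdr_alt: float,
                         hit_pvalue: float = HIT_PVALUE,
                         fc_threshold: float = FC_THRESHOLD,
                         fdr_threshold: float = FDR_THRESHOLD) -> str:
    """Concordance class of one annotated ASB.

    ``no_hit`` when neither allele's motif P value passes ``hit_pvalue``;
    ``weak`` when |FC| or the ASB FDR miss their thresholds (or either
    quantity is undefined/tied); else ``concordant`` when the ASB-preferred
    allele (smaller FDR) is the stronger-motif allele (smaller P value),
    ``discordant`` otherwise.
    """
    if min(pval_ref, pval_alt) > hit_pvalue:
        return "no_hit"
    if fc is None or not np.isfinite(fc) or abs(fc) < fc_threshold:
        return "weak"
    if min(fdr_ref, fdr_alt) > fdr_threshold or fdr_ref == fdr_alt:
        return "weak"
    alt_preferred = fdr_alt < fdr_ref
    alt_stronger_motif = fc > 0  # fc = log2(pval_ref / pval_alt)
    return "concordant" if alt_preferred == alt_stronger_motif else "discordant"


def annotate_snp(pwm: Pwm, context: str, snv_offset: int, ref_allele: str,
                 alt_allele: str, fdr_ref: float, fdr_alt: float,
                 hit_pvalue: float = HIT_PVALUE,
                 fc_threshold: float = FC_THRESHOLD,
                 fdr_threshold: float = FDR_THRESHOLD) -> dict:
    """Full motif annotation of one SNP: best hit, P values, FC, class."""
    hit = best_hit(pwm, context, snv_offset, ref_allele, alt_allele)
    pval_ref = pwm_score_pvalue(pwm, hit.score_ref)
    pval_alt = pwm_score_pvalue(pwm, hit.score_alt)
    fc = (math.log2(pval_ref / pval_alt)
          if pval_ref > 0 and pval_alt > 0 else None)
    cls = classify_concordance(fc, pval_ref, pval_alt, fdr_ref, fdr_alt,
                               hit_pvalue, fc_threshold, fdr_threshold)
    return {
        "pwm": pwm.name, "hit_offset": hit.offset, "hit_strand": hit.strand,
        "score_ref": hit.score_ref, "score_alt": hit.score_alt,
        "pval_ref": pval_ref, "pval_alt": pval_alt,
        "fc": np.nan if fc is None else fc, "class": cls,
    }


def annotate_table(agg: pd.DataFrame, pwms: dict[str, Pwm],
                   contexts: pd.DataFrame,
                   hit_pvalue: float = HIT_PVALUE,
                   fc_threshold: float = FC_THRESHOLD,
                   fdr_threshold: float = FDR_THRESHOLD) -> pd.DataFrame:
    """Annotate TF-level aggregated ASB calls with their TF's motif.

    ``contexts`` carries columns (chrom, pos, context, snv_offset); rows of
    ``agg`` whose TF has no PWM or whose site has no context are skipped.
    """
    ctx = {(r.chrom, r.pos): (r.context, int(r.snv_offset))
           for r in contexts.itertuples()}
    rows = []
    for r in agg.itertuples():
        pwm = pwms.get(r.group_name)
        key = (r.chrom, r.pos)
        if pwm is None or key not in ctx:
            continue
        context, off = ctx[key]
        ann = annotate_snp(pwm, context, off, r.ref_allele, r.alt_allele,
                           r.fdr_ref, r.fdr_alt, hit_pvalue, fc_threshold,
                           fdr_threshold)
        ann.update(chrom=r.chrom, pos=r.pos, ref_allele=r.ref_allele,
                   alt_allele=r.alt_allele, group_name=r.group_name,
                   fdr_ref=r.fdr_ref, fdr_alt=r.fdr_alt)
        rows.append(ann)
    return pd.DataFrame(rows, columns=[
        "chrom", "pos", "ref_allele", "alt_allele", "group_name", "pwm",
        "hit_offset", "hit_strand", "score_ref", "score_alt",
        "pval_ref", "pval_alt", "fc", "fdr_ref", "fdr_alt", "class"])
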