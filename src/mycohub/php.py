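"""Dual-evidence screening for potential metabolite-producing (PHP) ASVs.

Two independent lines of evidence are combined:

1. sequence identity: an ASV whose ITS2-like sequence aligns to a reference
   producer strain at >= 97% identity (semi-global alignment, terminal gaps
   free and excluded from the identity denominator, IUPAC ambiguity codes
   matching when their base sets intersect);
2. abundance-metabolite correlation: Kendall tau-b > 0.4 (strict) between an
   ASV's tissue-mean relative abundance and the tissue metabolite gradient.

The union of the two screens is the PHP call set; an ASV found by both
carries both evidence flags.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices
from scipy import stats

from .io import (
    AsvCountTable,
    MetaboliteTable,
    ReferenceStrainSet,
    SampleMetadata,
    SequenceSet,
)

_IUPAC_SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

DEFAULT_SCORING = {"match": 1.0, "mismatch": -1.0, "gap_open": -2.0, "gap_extend": -1.0}


@dataclass
class IdentityHit:
    asv_id: str
    strain_id: str
    identity: float  # percent, terminal-gap columns excluded
    alignment_columns: int


@dataclass
class PhpCall:
    asv_id: str
    evidence_clustering: bool
    evidence_correlation: bool
    best_identity: float | None = None
    tau: float | None = None


@dataclass
class PhpCallSet:
    calls: list[PhpCall]
    identity_min: float = 97.0
    tau_min: float = 0.4

    def __post_init__(self) -> None:
        ids = [c.asv_id for c in self.calls]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate ASV in PHP call set")
        for c in self.calls:
            if not (c.evidence_clustering or c.evidence_correlation):
                raise ValueError(f"{c.asv_id}: call without evidence")

    @property
    def asv_ids(self) -> set[str]:
        return {c.asv_id for c in self.calls}

    def counts(self) -> dict[str, int]:
        a = sum(c.evidence_clustering for c in self.calls)
        b = sum(c.evidence_correlation for c in self.calls)
        both = sum(c.evidence_clustering and c.evidence_correlation for c in self.calls)
        return {"n_clustering": a, "n_correlation": b, "n_both": both,
                "n_union": len(self.calls)}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "asv_id": c.asv_id,
                "evidence_clustering": c.evidence_clustering,
                "evidence_correlation": c.evidence_correlation,
                "best_identity": c.best_identity,
                "tau": c.tau,
            }
            for c in sorted(self.calls, key=lambda c: c.asv_id)
        ]
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# sequence identity screen


def _aligner(scoring: dict[str, float]) -> Align.PairwiseAligner:
    letters = "".join(_IUPAC_SETS)
    mat = substitution_matrices.Array(letters, dims=2)
    for a in letters:
        for b in letters:
            inter = set(_IUPAC_SETS[a]) & set(_IUPAC_SETS[b])
            mat[a, b] = scoring["match"] if inter else scoring["mismatch"]
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = mat
    # gap of length L costs |gap_open| + L * |gap_extend|
    aligner.open_gap_score = scoring["gap_open"] + scoring["gap_extend"]
    aligner.extend_gap_score = scoring["gap_extend"]
    # semi-global: terminal gaps free on both sequences
    aligner.end_insertion_score = 0.0
    aligner.end_deletion_score = 0.0
    aligner.mode = "global"
    return aligner


def _bases_match(a: str, b: str) -> bool:
    return bool(set(_IUPAC_SETS[a]) & set(_IUPAC_SETS[b]))


def pairwise_identity(
    query: str, reference: str, scoring: dict[str, float] | None = None
) -> tuple[float, int]:
    """Percent identity of the best semi-global alignment.

    Returns ``(identity, alignment_columns)`` where columns exclude terminal
    gaps (overhangs) but include internal gaps, and ambiguity codes count as
    matches when their base sets intersect.
    """
    if not query or not reference:
        raise ValueError("sequences must be non-empty")
    aligner = _aligner(scoring or DEFAULT_SCORING)
    aln = next(iter(aligner.align(query, reference)))
    row_q, row_r = str(aln[0]), str(aln[1])
    # trim terminal-gap columns: leading/trailing '-' runs in either row
    start = 0
    end = len(row_q)
    for row in (row_q, row_r):
        i = 0
        while i < len(row) and row[i] == "-":
            i += 1
        start = max(start, i)
        j = len(row)
        while j > 0 and row[j - 1] == "-":
            j -= 1
        end = min(end, j)
    if end <= start:
        return 0.0, 0
    matches = 0
    columns = end - start
    for a, b in zip(row_q[start:end], row_r[start:end]):
        if a != "-" and b != "-" and _bases_match(a, b):
            matches += 1
    return 100.0 * matches / columns, columns


def _edlib_identity_upper_bound(query: str, reference: str) -> float:
    """Fast optimistic percent-identity bound from the unit-cost edit distance."""
    res = edlib.align(query, reference, mode="HW", task="distance")
    d = res["editDistance"]
    n = min(len(query), len(reference))
    return 100.0 * max(0, n - d) / n if n else 0.0


def screen_by_identity(
    asv_seqs: SequenceSet,
    refs: ReferenceStrainSet,
    identity_min: float = 97.0,
    scoring: dict[str, float] | None = None,
    prefilter_margin: float = 5.0,
    min_coverage: float = 0.8,
) -> list[IdentityHit]:
    """Best reference hit per ASV, retained iff identity >= identity_min.

    Because terminal gaps are free, a chance overlap of a few bases would
    score 100% identity; a hit therefore must also cover at least
    ``min_coverage`` of the shorter sequence. Ties are broken by higher
    identity, then longer alignment, then lexicographic strain id. An
    edit-distance prefilter skips the affine alignment for pairs whose
    optimistic identity bound falls more than ``prefilter_margin`` points
    below the threshold.
    """
    if not asv_seqs.records or not refs.sequences.records:
        raise ValueError("empty sequence input")
    hits: list[IdentityHit] = []
    for asv_id, seq in asv_seqs.records.items():
        best: IdentityHit | None = None
        for strain_id in sorted(refs.ids):
            ref_seq = refs.sequences[strain_id]
            if prefilter_margin is not None:
                bound = _edlib_identity_upper_bound(seq, ref_seq)
                if bound < identity_min - prefilter_margin:
                    continue
            identity, cols = pairwise_identity(seq, ref_seq, scoring)
            if cols < min_coverage * min(len(seq), len(ref_seq)):
                continue
            cand = IdentityHit(asv_id, strain_id, identity, cols)
            if best is None or (cand.identity, cand.alignment_columns) > (
                best.identity, best.alignment_columns
            ):
                best = cand
        if best is not None and best.identity >= identity_min:
            hits.append(best)
    return hits


# ---------------------------------------------------------------------------
# correlation screen


def tissue_mean_abundance(
    table: AsvCountTable, meta: SampleMetadata, percent: bool = True
) -> pd.DataFrame:
    """tissue x ASV matrix of mean per-sample relative abundances."""
    rel = table.relative(percent=percent)
    tissues = meta.tissue_of().loc[rel.index]
    return rel.groupby(tissues).mean()


def kendall_tau_b(x, y) -> float | None:
    """Kendall tau-b with tie correction; None when either vector is all-tied."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("need two equal-length vectors of size >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return None
    tau = stats.kendalltau(x, y, variant="b").statistic
    return None if math.isnan(tau) else float(tau)


def screen_by_correlation(
    tissue_means: pd.DataFrame,
    metabolites: MetaboliteTable,
    compound: str,
    tau_min: float = 0.4,
) -> dict[str, float]:
    """ASVs whose tissue-mean abundance has tau-b strictly above ``tau_min``.

    Zero-abundance tissues are included in the correlation vectors; constant
    ASVs have undefined tau and are never retained.
    """
    grad = metabolites.gradient(compound)
    common = [t for t in tissue_means.index if t in grad.index]
    if set(tissue_means.index) != set(grad.index):
        missing = set(tissue_means.index) ^ set(grad.index)
        raise ValueError(f"tissue sets differ between abundance and metabolites: {sorted(missing)}")
    if len(common) < 3:
        raise ValueError("need at least 3 tissues for a correlation screen")
    g = grad.loc[common].to_numpy()
    out: dict[str, float] = {}
    for asv in tissue_means.columns:
        tau = kendall_tau_b(tissue_means.loc[common, asv].to_numpy(), g)
        if tau is not None and tau > tau_min:
            out[asv] = tau
    return out


def merge_php_calls(
    from_identity: list[IdentityHit],
    from_correlation: dict[str, float],
    identity_min: float = 97.0,
    tau_min: float = 0.4,
) -> PhpCallSet:
    """Union of the two evidence sets, preserving per-ASV evidence flags."""
    best_by_asv = {h.asv_id: h for h in from_identity}
    calls = []
    for asv in sorted(set(best_by_asv) | set(from_correlation)):
        calls.append(
            PhpCall(
                asv_id=asv,
                evidence_clustering=asv in best_by_asv,
                evidence_correlation=asv in from_correlation,
                best_identity=best_by_asv[asv].identity if asv in best_by_asv else None,
                tau=from_correlation.get(asv),
            )
        )
    return PhpCallSet(calls, identity_min=identity_min, tau_min=tau_min)


def php_tissue_summary(
    calls: PhpCallSet, table: AsvCountTable, meta: SampleMetadata
) -> pd.DataFrame:
    """Per-tissue detected-ASV and PHP counts with rounded percentages.

    An ASV counts as detected in a tissue iff it has a nonzero count in at
    least one sample of that tissue; percentages are rounded half-up to two
    decimals.
    """
    from decimal import Decimal, ROUND_HALF_UP

    tissues = meta.tissue_of().loc[table.counts.index]
    php = calls.asv_ids
    rows = []
    for tissue, sub in table.counts.groupby(tissues):
        detected = set(sub.columns[(sub > 0).any(axis=0)])
        n_php = len(detected & php)
        if detected:
            pct = float(
                Decimal(100.0 * n_php / len(detected)).quantize(
                    Decimal("0.01"), rounding=ROUND_HALF_UP
                )
            )
        else:
            pct = 0.0
        rows.append(
            {
                "tissue": tissue,
                "n_asvs_detected": len(detected),
                "n_php": n_php,
                "percent_php": pct,
            }
        )
    return pd.DataFrame(rows).set_index("tissue")


def discover_php(
    asv_seqs: SequenceSet,
    refs: ReferenceStrainSet,
    table: AsvCountTable,
    meta: SampleMetadata,
    metabolites: MetaboliteTable,
    compound: str = "HupA",
    identity_min: float = 97.0,
    tau_min: float = 0.4,
) -> PhpCallSet:
    """Run both screens on one dataset and merge the evidence."""
    hits = screen_by_identity(asv_seqs, refs, identity_min=identity_min)
    means = tissue_mean_abundance(table, meta)
    corr = screen_by_correlation(means, metabolites, compound, tau_min=tau_min)
    return merge_php_calls(hits, corr, identity_min=identity_min, tau_min=tau_min)
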