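"""Differential expression between tag libraries.

The caller compares a gene's tag count x (out of N1 clean tags in library
1) with its count y (out of N2 in library 2) using the Audic-Claverie
exact statistic: conditional on x, the probability of observing y in the
second library is

    p(y | x) = (N2/N1)^y * (x+y)! / ( x! * y! * (1 + N2/N1)^(x+y+1) ),

which is the negative-binomial mass with size x+1 and success probability
N1/(N1+N2).  Two-sided significance is the doubled smaller tail,

    p = min(1, 2 * min( sum_{k<=y} p(k|x), sum_{k>=y} p(k|x) )),

computed in log space with chunked summation of the smaller tail (the
other tail follows by complementation through the point mass, so no long
sum against the mode is ever needed).

Genes pass at the conventional tag-profiling thresholds FDR <= 0.001
(Benjamini-Hochberg over all tested genes of the comparison) and
|log2Ratio| >= 1, where log2Ratio = log2(TPM2/TPM1) with a small TPM floor
substituted for zeros so condition-specific genes get finite ratios.

The module also provides the cross-comparison overlap summary
(coordinated vs antagonistic regulation) and the 2^-ddCt fold-change
arithmetic used for qPCR validation of tag-based calls.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

from .tagmap import ExpressionTable

_CHUNK = 2048
_TINY = 5e-324  # smallest positive subnormal; keeps p in (0, 1]

UP = "up"
DOWN = "down"
NONE = "none"


def _log_pmf(k: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    """log p(k | x) of the Audic-Claverie predictive distribution."""
    return (
        k * log_r
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * log_1pr
    )


def _tail_logsum(x: int, y: int, log_r: float, log_1pr: float, upper: bool) -> float:
    """log of sum_{k<=y} p(k|x) (upper=False) or sum_{k>=y} p(k|x) (upper=True).

    Summed away from the mode in chunks; terms decay geometrically there,
    so the sum converges after a few chunks even for large counts.
    """
    total = -np.inf
    k0 = y
    while True:
        if upper:
            ks = np.arange(k0, k0 + _CHUNK)
        else:
            lo = max(0, k0 - _CHUNK + 1)
            ks = np.arange(lo, k0 + 1)
        chunk = logsumexp(_log_pmf(ks, x, log_r, log_1pr))
        total = np.logaddexp(total, chunk)
        if not upper and ks[0] == 0:
            break
        # remaining terms are bounded by a geometric tail; stop once the
        # last chunk no longer moves the running sum
        if chunk < total - 45.0:
            break
        k0 = ks[-1] + 1 if upper else ks[0] - 1
        if not upper and k0 < 0:
            break
    return float(total)


def ac_pvalue(x: int, y: int, n1: int, n2: int) -> float:
    """Two-sided Audic-Claverie p-value for counts x (of n1) vs y (of n2).

    Exact up to floating point: the smaller tail is summed directly and
    the opposite tail recovered as 1 - tail + p(y|x).  Symmetric in the
    sense ac_pvalue(x, y, n1, n2) == ac_pvalue(y, x, n2, n1).
    """
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    if n1 < 1 or n2 < 1:
        raise ValueError("library totals must be >= 1")
    log_r = math.log(n2) - math.log(n1)
    log_1pr = math.log1p(n2 / n1)
    p_y = math.exp(_log_pmf(np.array([y]), x, log_r, log_1pr)[0])
    mean = (x + 1) * (n2 / n1)
    if y <= mean:
        lower = math.exp(_tail_logsum(x, y, log_r, log_1pr, upper=False))
        upper = 1.0 - lower + p_y
    else:
        upper = math.exp(_tail_logsum(x, y, log_r, log_1pr, upper=True))
        lower = 1.0 - upper + p_y
    p = 2.0 * min(lower, upper)
    return max(min(p, 1.0), _TINY)


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class DEComparison:
    """Per-gene differential-expression calls for one library pair.

    ``data`` is indexed by gene_id with columns x, y, tpm1, tpm2,
    log2_ratio, p_value, fdr, significant, direction.  Direction "up"
    means higher expression in the second (treatment) library.
    """

    library_1: str
    library_2: str
    n1: int
    n2: int
    data: pd.DataFrame
    params: dict = field(default_factory=dict)

    @property
    def significant_genes(self) -> set[str]:
        return set(self.data.index[self.data["significant"]])

    @property
    def n_de(self) -> int:
        return int(self.data["significant"].sum())

    @property
    def n_up(self) -> int:
        return int((self.data["direction"] == UP).sum())

    @property
    def n_down(self) -> int:
        return int((self.data["direction"] == DOWN).sum())

    def directions(self) -> dict[str, str]:
        return self.data["direction"].to_dict()


def compare_libraries(
    table1: ExpressionTable,
    table2: ExpressionTable,
    fdr_cut: float = 0.001,
    lfc_cut: float = 1.0,
    tpm_floor: float = 0.001,
) -> DEComparison:
    """Audic-Claverie differential expression, library 2 vs library 1.

    The tested universe is the union of genes with sense signal in either
    library (genes undetected in both carry no information and would only
    dilute the BH correction).  ``tpm_floor`` replaces zero TPM values
    before forming log2Ratio so condition-specific genes get finite,
    comparable ratios; it never alters non-zero values.
    """
    if table1.library_id == table2.library_id:
        raise ValueError("comparing a library to itself")
    c1 = table1.data["sense_count"]
    c2 = table2.data["sense_count"]
    genes = sorted(set(c1.index[c1 > 0]) | set(c2.index[c2 > 0]))
    n1, n2 = table1.clean_total, table2.clean_total
    if n1 < 1 or n2 < 1:
        raise ValueError("clean totals must be positive")
    x = np.array([int(c1.get(g, 0)) for g in genes])
    y = np.array([int(c2.get(g, 0)) for g in genes])
    tpm1 = x / n1 * 1e6
    tpm2 = y / n2 * 1e6
    f1 = np.where(tpm1 == 0, tpm_floor, tpm1)
    f2 = np.where(tpm2 == 0, tpm_floor, tpm2)
    lr = np.log2(f2 / f1)
    p = np.array([ac_pvalue(int(a), int(b), n1, n2) for a, b in zip(x, y)])
    fdr = bh_fdr(p) if len(p) else np.array([])
    sig = (fdr <= fdr_cut) & (np.abs(lr) >= lfc_cut)
    direction = np.where(~sig, NONE, np.where(lr > 0, UP, DOWN))
    data = pd.DataFrame(
        {
            "x": x, "y": y, "tpm1": tpm1, "tpm2": tpm2,
            "log2_ratio": lr, "p_value": p, "fdr": fdr,
            "significant": sig, "direction": direction,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return DEComparison(
        table1.library_id, table2.library_id, n1, n2, data,
        params={"fdr_cut": fdr_cut, "lfc_cut": lfc_cut, "tpm_floor": tpm_floor},
    )


@dataclass(frozen=True)
class OverlapSummary:
    """Shared differential-expression calls between two comparisons."""

    n_de_a: int
    n_up_a: int
    n_down_a: int
    n_de_b: int
    n_up_b: int
    n_down_b: int
    n_shared: int
    n_coordinated: int
    n_antagonistic: int
    shared_genes: frozenset[str] = frozenset()
    antagonistic_genes: frozenset[str] = frozenset()


def overlap_summary(comp_a: DEComparison, comp_b: DEComparison) -> OverlapSummary:
    """Venn-style accounting of two DE comparisons over a shared universe.

    A shared gene is coordinated when both comparisons call it in the same
    direction, antagonistic otherwise.
    """
    sa, sb = comp_a.significant_genes, comp_b.significant_genes
    shared = sa & sb
    da, db = comp_a.directions(), comp_b.directions()
    coordinated = {g for g in shared if da[g] == db[g]}
    antagonistic = shared - coordinated
    return OverlapSummary(
        n_de_a=comp_a.n_de, n_up_a=comp_a.n_up, n_down_a=comp_a.n_down,
        n_de_b=comp_b.n_de, n_up_b=comp_b.n_up, n_down_b=comp_b.n_down,
        n_shared=len(shared),
        n_coordinated=len(coordinated),
        n_antagonistic=len(antagonistic),
        shared_genes=frozenset(shared),
        antagonistic_genes=frozenset(antagonistic),
    )


@dataclass(frozen=True)
class QpcrRecord:
    """Cycle-threshold quartet for one gene's qPCR validation."""

    ct_target_treated: float
    ct_reference_treated: float
    ct_target_control: float
    ct_reference_control: float


def ddct_fold_change(record: QpcrRecord) -> float:
    """Relative expression by the 2^-ddCt method.

    ddCt = (Ct_target - Ct_reference)_treated - (Ct_target - Ct_reference)_control;
    the fold change is 2^-ddCt, normalised to the reference gene and the
    control condition.
    """
    cts = (
        record.ct_target_treated, record.ct_reference_treated,
        record.ct_target_control, record.ct_reference_control,
    )
    if not all(math.isfinite(c) for c in cts):
        raise ValueError("all Ct values must be finite")
    d_treated = record.ct_target_treated - record.ct_reference_treated
    d_control = record.ct_target_control - record.ct_reference_control
    return 2.0 ** -(d_treated - d_control)
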