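"""Chemical-class shift analysis, interface-usage classification and the
shared statistical toolkit (Fisher, chi-square, hypergeometric, BH-FDR,
rank-sum).

The statistical routines wrap scipy behind a stable surface so that every
analysis in the package reports tests the same way; the chemical-class
table is configuration, not dogma — amino-acid class boundaries differ
between textbooks, so shift analyses should always record the table used.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structmap import MutationRecord

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_CHEMICAL_CLASSES",
    "CHEMICAL_CLASS_NAMES",
    "InterfaceUsage",
    "chemical_class",
    "class_shift",
    "shift_matrix",
    "classify_interface_usage",
    "fisher_exact_2x2",
    "chi_square",
    "hypergeometric_upper",
    "bh_fdr",
    "ranksum_compare",
]

CHEMICAL_CLASS_NAMES = ("hydrophobic", "charged", "polar")

#: Default amino-acid chemistry: charged {D,E,K,R,H}, polar {S,T,N,Q,C,Y},
#: hydrophobic the rest (incl. G and P).
DEFAULT_CHEMICAL_CLASSES: dict[str, str] = {}
for _aa in "DEKRH":
    DEFAULT_CHEMICAL_CLASSES[_aa] = "charged"
for _aa in "STNQCY":
    DEFAULT_CHEMICAL_CLASSES[_aa] = "polar"
for _aa in "AVLIMFWPG":
    DEFAULT_CHEMICAL_CLASSES[_aa] = "hydrophobic"


def chemical_class(aa: str, table: Mapping[str, str] | None = None) -> str:
    """Chemical class of a 1-letter amino acid under ``table``."""
    table = DEFAULT_CHEMICAL_CLASSES if table is None else table
    if aa not in table:
        raise ValueError(f"nonstandard amino acid {aa!r}")
    return table[aa]


def class_shift(
    ref_aa: str,
    alt_aa: str,
    table: Mapping[str, str] | None = None,
) -> tuple[str, str, bool]:
    """(ref class, alt class, preserved) for a missense substitution."""
    ref_c = chemical_class(ref_aa, table)
    alt_c = chemical_class(alt_aa, table)
    return ref_c, alt_c, ref_c == alt_c


def shift_matrix(
    mutations: Sequence[MutationRecord],
    table: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """3x3 chemical-class shift matrix (rows = wild type, cols = mutant).

    Only missense records contribute; nonsense/frameshift records have no
    alternate residue and are skipped with a log message. Row sums therefore
    equal the per-ref-class missense counts.
    """
    mat = pd.DataFrame(
        0, index=list(CHEMICAL_CLASS_NAMES), columns=list(CHEMICAL_CLASS_NAMES)
    )
    skipped = 0
    for m in mutations:
        if m.mutation_type != "missense":
            skipped += 1
            continue
        ref_c, alt_c, _ = class_shift(m.ref_aa, m.alt_aa, table)
        mat.at[ref_c, alt_c] += 1
    if skipped:
        logger.info("shift_matrix: skipped %d non-missense records", skipped)
    return mat


# ---------------------------------------------------------------------------
# interface usage


@dataclass
class InterfaceUsage:
    """How a protein's mutations distribute over its binding interfaces.

    ``one-one``: a single mutated interface with a single partner.
    ``one-shared``: a single mutated interface shared by several partners
    (overlapping binding regions). ``multi``: two or more distinct mutated
    interfaces, typically used by different partner subsets.
    """

    protein: str
    usage: str  # 'one-one' | 'one-shared' | 'multi'
    interfaces: dict[str, tuple[set[str], set[tuple[str, int]]]]


def classify_interface_usage(
    protein: str,
    interfaces: Mapping[str, tuple[set[str], set[tuple[str, int]]]],
) -> InterfaceUsage:
    """Classify a protein by its mutated interfaces.

    ``interfaces`` maps interface id -> (partner set, mutation site set);
    only interfaces with at least one mutation participate.
    """
    mutated = {k: v for k, v in interfaces.items() if v[1]}
    if not mutated:
        raise ValueError(f"protein {protein} has no mutated interface")
    if len(mutated) >= 2:
        usage = "multi"
    else:
        (partners, _sites), = mutated.values()
        usage = "one-shared" if len(partners) >= 2 else "one-one"
    return InterfaceUsage(protein, usage, dict(mutated))


# ---------------------------------------------------------------------------
# statistics


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 table.

    Returns (odds ratio, p). OR = ad/bc (inf when bc = 0); the two-sided p
    sums hypergeometric probabilities of all tables with fixed margins whose
    probability does not exceed the observed one. Degenerate margins give
    p = 1 and OR = nan.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 table")
    (a, b), (c, d) = t
    if min(t.sum(axis=0).min(), t.sum(axis=1).min()) == 0:
        return float("nan"), 1.0
    odds = math.inf if b * c == 0 else (a * d) / (b * c)
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return odds, float(p)


def chi_square(table: Sequence[Sequence[int]]) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction.

    Zero-margin rows/columns are dropped with a warning before testing.
    Returns (statistic, degrees of freedom, p).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if t.sum() <= 0:
        raise ValueError("table total must be positive")
    rows = t.sum(axis=1) > 0
    cols = t.sum(axis=0) > 0
    if not rows.all() or not cols.all():
        logger.warning("chi_square: dropping zero-margin rows/columns")
        t = t[rows][:, cols]
        if t.shape[0] < 2 or t.shape[1] < 2:
            return 0.0, 0, 1.0
    stat, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(stat), int(df), float(p)


def hypergeometric_upper(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``k`` observed successes among ``n`` draws from a population of ``N``
    containing ``K`` successes.
    """
    if not (0 <= k <= n <= N and k <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone, order-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return stats.false_discovery_control(p, method="bh")


def ranksum_compare(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> tuple[float, float]:
    """Mann–Whitney U, two-sided.

    Small untied samples use the exact U distribution; larger or tied ones
    the tie-corrected normal approximation. Returns (U statistic of the
    first sample, p).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
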