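"""Network-guided patient stratification and survival comparison.

Each patient's reconstructed subnetwork is reduced to a pathway
over-representation profile (hypergeometric test against the interactome
universe, BH-corrected); the per-patient enrichment scores form a
pathway-by-patient matrix that is factorized (NMF) and consensus-clustered
into k patient groups. Groups are then compared on survival (Kaplan-Meier /
log-rank) and searched for over-represented mutation patches.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import NMF

from .mutchar import bh_fdr, hypergeometric_upper

logger = logging.getLogger(__name__)

__all__ = [
    "ClusterConfig",
    "SurvivalRecord",
    "DEFAULT_DISEASE_BLOCKLIST",
    "read_gmt",
    "write_gmt",
    "pathway_ora",
    "build_es_matrix",
    "nmf",
    "consensus_cluster",
    "km_estimate",
    "logrank_test",
    "patch_group_enrichment",
]

#: Name patterns of disease/phenotype pathways removed before profiling:
#: enrichment of e.g. generic cancer pathways carries no stratification
#: signal in a tumor cohort.
DEFAULT_DISEASE_BLOCKLIST: tuple[str, ...] = ("infection", "cancer", "addiction")


@dataclass
class ClusterConfig:
    """Consensus-clustering settings.

    k: number of patient groups.
    n_iterations: subsampled NMF repetitions aggregated into the consensus.
    subsample_fraction: fraction of patients drawn (without replacement)
        per repetition.
    nmf_max_iter / nmf_tol: multiplicative-update stopping rule.
    seed: master seed; every repetition derives from it deterministically.
    """

    k: int = 5
    n_iterations: int = 100
    subsample_fraction: float = 0.8
    nmf_max_iter: int = 500
    nmf_tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if not 0.0 < self.subsample_fraction <= 1.0:
            raise ValueError("subsample fraction must lie in (0, 1]")


@dataclass(frozen=True)
class SurvivalRecord:
    patient: str
    time: float          # days
    event: int           # 1 = death observed, 0 = censored
    group: str = ""

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("survival time must be non-negative")


# ---------------------------------------------------------------------------
# pathway sets


def read_gmt(path_or_buffer) -> dict[str, set[str]]:
    """Read GMT gene sets: name <tab> description <tab> gene ...."""
    sets: dict[str, set[str]] = {}
    if hasattr(path_or_buffer, "read"):
        lines = path_or_buffer.read().splitlines()
    else:
        with open(path_or_buffer) as fh:
            lines = fh.read().splitlines()
    for line in lines:
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = set(fields[2:])
    return sets


def write_gmt(sets: Mapping[str, Iterable[str]], path) -> None:
    with open(path, "w") as fh:
        for name in sets:
            genes = "\t".join(sorted(sets[name]))
            fh.write(f"{name}\tsynthetic\t{genes}\n")


# ---------------------------------------------------------------------------
# over-representation


def pathway_ora(
    network_nodes: Iterable[str],
    pathway_sets: Mapping[str, set[str]],
    universe: Iterable[str],
    fdr_threshold: float = 0.1,
    disease_blocklist: Sequence[str] = DEFAULT_DISEASE_BLOCKLIST,
) -> pd.DataFrame:
    """Hypergeometric over-representation of pathways in one network.

    The universe is the filtered interactome's protein set; network nodes
    outside it are intersected away with a warning. Pathways whose names
    match the disease blocklist (case-insensitive substring) are removed
    before testing, so they never consume FDR budget. The enrichment score
    ES is the observed/expected overlap ratio; ``enriched`` marks pathways
    with BH q below ``fdr_threshold``.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    nodes = set(network_nodes)
    outside = nodes - universe
    if outside:
        logger.warning("%d network nodes outside universe dropped", len(outside))
        nodes &= universe

    block = [re.compile(p, re.IGNORECASE) for p in disease_blocklist]
    rows = []
    for name, members in pathway_sets.items():
        if any(b.search(name) for b in block):
            continue
        in_universe = members & universe
        if not in_universe:
            continue
        overlap = len(nodes & in_universe)
        if nodes:
            p = hypergeometric_upper(overlap, len(in_universe), len(nodes), len(universe))
            expected = len(in_universe) / len(universe)
            es = (overlap / len(nodes)) / expected
        else:
            p, es = 1.0, 0.0
        rows.append({"pathway": name, "overlap": overlap, "es": es, "p": p})
    result = pd.DataFrame(rows, columns=["pathway", "overlap", "es", "p"])
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
        result["enriched"] = result["q"] < fdr_threshold
    else:
        result["q"] = pd.Series(dtype=float)
        result["enriched"] = pd.Series(dtype=bool)
    return result


def build_es_matrix(per_patient: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Pathway-by-patient enrichment-score matrix.

    Rows are the union of pathways enriched in at least one patient (sorted
    for reproducibility); columns follow the input patient order. An entry
    holds the ES when that pathway passed the FDR threshold for that
    patient and 0 otherwise. Patients with all-zero columns are logged —
    they carry no pathway signal and are excluded from clustering.
    """
    enriched_union: set[str] = set()
    for df in per_patient.values():
        enriched_union |= set(df.loc[df["enriched"], "pathway"])
    index = sorted(enriched_union)
    matrix = pd.DataFrame(0.0, index=index, columns=list(per_patient))
    for patient, df in per_patient.items():
        hits = df.loc[df["enriched"]]
        for _, row in hits.iterrows():
            matrix.at[row["pathway"], patient] = row["es"]
    empty = [p for p in matrix.columns if matrix[p].sum() == 0]
    if empty:
        logger.info("%d patients have all-zero enrichment profiles", len(empty))
    return matrix


# ---------------------------------------------------------------------------
# clustering


def nmf(
    matrix: np.ndarray | pd.DataFrame,
    k: int,
    max_iter: int = 500,
    tol: float = 1e-6,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative matrix factorization X ~ W @ H (Frobenius loss,
    multiplicative updates, random seeded init; no network regularizer)."""
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("matrix entries must be non-negative")
    if k > min(X.shape):
        raise ValueError("k exceeds matrix rank bound")
    model = NMF(
        n_components=k,
        solver="mu",
        beta_loss="frobenius",
        init="random",
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    W = model.fit_transform(X)
    H = model.components_
    return W, H


def consensus_cluster(
    matrix: pd.DataFrame,
    config: ClusterConfig,
) -> tuple[pd.Series, pd.DataFrame]:
    """Consensus clustering of patients by repeated subsampled NMF.

    Each repetition subsamples ceil(fraction * n) patients without
    replacement, factorizes their columns and assigns each sampled patient
    to its argmax H component. The consensus entry for a patient pair is the
    number of co-clusterings over the number of co-samplings; final labels
    cut an average-linkage dendrogram of (1 - consensus) into k groups.
    All-zero columns must be removed beforehand.
    """
    patients = list(matrix.columns)
    n = len(patients)
    nonzero = (matrix.sum(axis=0) > 0).sum()
    if nonzero < config.k:
        raise ValueError("fewer non-zero patient columns than k")
    rng = np.random.default_rng(config.seed)
    m = int(np.ceil(config.subsample_fraction * n))

    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    X = matrix.to_numpy(dtype=float)
    for it in range(config.n_iterations):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = X[:, idx]
        keep = sub.sum(axis=0) > 0
        idx = idx[keep]
        if len(idx) < config.k:
            continue
        _, H = nmf(
            X[:, idx],
            config.k,
            max_iter=config.nmf_max_iter,
            tol=config.nmf_tol,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        assign = H.argmax(axis=0)
        co_sample[np.ix_(idx, idx)] += 1
        for c in range(config.k):
            members = idx[assign == c]
            co_cluster[np.ix_(members, members)] += 1

    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    dist = 1.0 - consensus
    np.fill_diagonal(dist, 0.0)
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=config.k, criterion="maxclust")
    label_series = pd.Series(
        [f"cluster-{c}" for c in labels], index=patients, name="group"
    )
    consensus_df = pd.DataFrame(consensus, index=patients, columns=patients)
    return label_series, consensus_df


# ---------------------------------------------------------------------------
# survival


def km_estimate(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    """Kaplan-Meier product-limit survival curve.

    Returns a step table (time, survival) starting at S(0) = 1; censored
    observations contribute to the risk set without forcing a step.
    """
    if not records:
        raise ValueError("no survival records")
    times = [r.time for r in records]
    events = [r.event for r in records]
    fitter = KaplanMeierFitter()
    fitter.fit(times, events)
    sf = fitter.survival_function_
    return pd.DataFrame(
        {"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()}
    )


def logrank_test(records: Sequence[SurvivalRecord]) -> tuple[float, int, float]:
    """k-sample log-rank test across the groups in ``records``.

    Returns (chi-square statistic, degrees of freedom, p). If no event was
    observed at all the test is undefined and (0, df, 1) is returned with a
    warning.
    """
    groups = sorted({r.group for r in records})
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for g in groups:
        if not any(r.group == g for r in records):
            raise ValueError(f"group {g} is empty")
    if not any(r.event for r in records):
        logger.warning("log-rank: all observations censored")
        return 0.0, len(groups) - 1, 1.0
    df = pd.DataFrame(
        {
            "time": [r.time for r in records],
            "event": [r.event for r in records],
            "group": [r.group for r in records],
        }
    )
    res = multivariate_logrank_test(df["time"], df["group"], df["event"])
    return float(res.test_statistic), len(groups) - 1, float(res.p_value)


# ---------------------------------------------------------------------------
# patch enrichment per group


def patch_group_enrichment(
    presence: pd.DataFrame,
    groups: Mapping[str, str],
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Which patches over-represent which patient group (hypergeometric).

    For each (patch, group): draws = group size, successes = patch carriers,
    population = all grouped patients. BH correction runs across every
    tested pair; pairs with q below ``q_threshold`` are the group's
    signature patches. Ungrouped patients must be excluded from ``groups``
    beforehand.
    """
    patients = [p for p in presence.columns if p in groups]
    sub = presence[patients]
    group_ids = sorted(set(groups[p] for p in patients))
    N = len(patients)
    rows = []
    for patch in sub.index:
        carriers = {p for p in patients if sub.at[patch, p]}
        for gid in group_ids:
            members = {p for p in patients if groups[p] == gid}
            k = len(carriers & members)
            p_val = hypergeometric_upper(k, len(carriers), len(members), N)
            rows.append(
                {
                    "patch": patch,
                    "group": gid,
                    "carriers_in_group": k,
                    "carriers_total": len(carriers),
                    "group_size": len(members),
                    "p": p_val,
                }
            )
    result = pd.DataFrame(rows)
    if len(result):
        result["q"] = bh_fdr(result["p"].to_numpy())
        result["signature"] = result["q"] < q_threshold
    return result
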