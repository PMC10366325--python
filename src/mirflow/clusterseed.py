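"""Cluster and seed-family contributions to the miRNA population.

For each cell state, the contribution of a genomic cluster (or seed family)
is the fraction of the state's total normalized miRNA reads carried by the
unit's members, using the mean normalized count over the state's replicates
so the statistic is invariant to replicate number.  The module also
summarises cross-cluster seed similarity (best member pair per cluster pair)
and the effective number of expressed units (exponential Shannon entropy),
which quantifies how spread the population is across clusters.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .annotation import AnnotatedMiRNA, ClusterTable, seed_similarity

UNASSIGNED = "unassigned"


def _contributions(
    type_means: pd.DataFrame, unit_of: Mapping[str, str]
) -> pd.DataFrame:
    """Long-format fractions per (cell_type, unit_id), plus 'unassigned'."""
    rows = []
    units = type_means.index.map(lambda m: unit_of.get(m, UNASSIGNED))
    for ct in type_means.columns:
        total = type_means[ct].sum()
        if total <= 0:
            raise ValueError(f"cell type {ct} has zero total normalized counts")
        shares = type_means[ct].groupby(units).sum() / total
        for unit_id, frac in shares.items():
            rows.append({"cell_type": ct, "unit_id": unit_id, "fraction": float(frac)})
        if UNASSIGNED not in shares.index:
            rows.append({"cell_type": ct, "unit_id": UNASSIGNED, "fraction": 0.0})
    df = pd.DataFrame(rows)
    return df.sort_values(["cell_type", "fraction"], ascending=[True, False]).reset_index(
        drop=True
    )


def cluster_contributions(norm, clusters: ClusterTable) -> pd.DataFrame:
    """Fraction of each cell type's normalized reads per genomic cluster.

    Cluster members absent from the matrix are warned about and skipped;
    miRNAs in no cluster are pooled under 'unassigned'.
    """
    type_means = norm.type_means()
    unit_of = {}
    for cid, members in clusters.members.items():
        for m in members:
            if m not in type_means.index:
                warnings.warn(f"cluster member {m} not in count matrix; skipped")
                continue
            unit_of[m] = cid
    return _contributions(type_means, unit_of)


def family_contributions(norm, families: Mapping[str, Iterable[str]]) -> pd.DataFrame:
    """As cluster_contributions with seed families; every miRNA has exactly
    one family, so the unassigned share is zero when families cover the
    matrix."""
    type_means = norm.type_means()
    unit_of = {}
    for fid, members in families.items():
        for m in members:
            if m in type_means.index:
                unit_of[m] = fid
    return _contributions(type_means, unit_of)


def contribution_of(contrib: pd.DataFrame, cell_type: str, unit_id: str) -> float:
    sel = contrib[(contrib["cell_type"] == cell_type) & (contrib["unit_id"] == unit_id)]
    return float(sel["fraction"].iloc[0]) if len(sel) else 0.0


def cluster_seed_report(
    clusters: ClusterTable, mirnas: Iterable[AnnotatedMiRNA]
) -> pd.DataFrame:
    """Best seed-similarity pair for every pair of clusters.

    For each (cluster_a, cluster_b) the member pair with the maximal
    longest-common-substring score is reported with its category
    (identical / similar / dissimilar).  The diagonal compares a cluster
    with itself and is identical by construction.
    """
    seed_of: dict[str, str] = {}
    for m in mirnas:
        seed_of.setdefault(m.mirna_id, m.seed)
    cids = sorted(clusters.members)
    rows = []
    for ca in cids:
        for cb in cids:
            best = (-1, None, None, -1)
            best_cat = None
            for ma in clusters.members[ca]:
                for mb in clusters.members[cb]:
                    if ma not in seed_of or mb not in seed_of:
                        continue
                    cat, score = seed_similarity(seed_of[ma], seed_of[mb])
                    key = (score, 1 if cat == "identical" else 0)
                    if (best[0], best[3]) < key:
                        best = (score, ma, mb, 1 if cat == "identical" else 0)
                        best_cat = cat
            if best[1] is None:
                continue
            rows.append(
                {
                    "cluster_a": ca,
                    "cluster_b": cb,
                    "best_mirna_a": best[1],
                    "best_mirna_b": best[2],
                    "score": best[0],
                    "category": best_cat,
                }
            )
    return pd.DataFrame(rows)


def diversity_summary(contrib: pd.DataFrame, top_k: int = 3) -> pd.DataFrame:
    """Per cell type: top-k units by fraction, their cumulative fraction, and
    the effective number of units exp(H) over non-zero unit fractions
    (the 'unassigned' pool counts as one unit)."""
    rows = []
    for ct, grp in contrib.groupby("cell_type", sort=False):
        grp = grp.sort_values(["fraction", "unit_id"], ascending=[False, True])
        fracs = grp["fraction"].to_numpy()
        nz = fracs[fracs > 0]
        entropy = float(-(nz * np.log(nz)).sum())
        top = grp.head(top_k)
        rows.append(
            {
                "cell_type": ct,
                "top_units": ",".join(top["unit_id"]),
                "top_cumulative_fraction": float(top["fraction"].sum()),
                "effective_n_units": float(np.exp(entropy)),
            }
        )
    return pd.DataFrame(rows)
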