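"""Eight-group expression-trajectory classification across two transitions.

Each miRNA is scored on two contrasts — (1) self-renewing NSC vs hESC and
(2) differentiating NSC vs NSC — and each transition is called UP (padj <
0.05 and log2FC > +0.6), DOWN (padj < 0.05 and log2FC < -0.6) or STABLE.
The (state1, state2) pair maps to one of eight trajectory groups:

    (UP, DOWN) -> G1      NSC-specific up          (DOWN, UP)   -> G2
    (UP, UP)   -> G3      rising throughout        (UP, STABLE) -> G4
    (DOWN, DOWN) -> G5    falling throughout       (DOWN, STABLE) -> G6
    (STABLE, UP) -> G7    changes only at terminal (STABLE, DOWN) -> G8

(STABLE, STABLE) is unclassified.  The mapping is data, not code: pass any
injective mapping over the eight non-stable pairs to override the default.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

DEFAULT_GROUP_MAPPING: dict[tuple[str, str], str] = {
    ("UP", "DOWN"): "G1",
    ("DOWN", "UP"): "G2",
    ("UP", "UP"): "G3",
    ("UP", "STABLE"): "G4",
    ("DOWN", "DOWN"): "G5",
    ("DOWN", "STABLE"): "G6",
    ("STABLE", "UP"): "G7",
    ("STABLE", "DOWN"): "G8",
}

UNCLASSIFIED = "unclassified"


def transition_state(padj: float, log2fc: float, p_thresh: float, fc_thresh: float) -> str:
    """UP/DOWN require significance and a fold change strictly beyond the
    threshold; everything else is STABLE."""
    if not np.isnan(padj) and padj < p_thresh:
        if log2fc > fc_thresh:
            return "UP"
        if log2fc < -fc_thresh:
            return "DOWN"
    return "STABLE"


def load_group_mapping(path: str | Path) -> dict[tuple[str, str], str]:
    """Read a mapping TSV with columns state1, state2, group."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    mapping = {(r.state1, r.state2): r.group for r in df.itertuples()}
    _validate_mapping(mapping)
    return mapping


def _validate_mapping(mapping: Mapping[tuple[str, str], str]) -> None:
    pairs = [p for p in mapping if p != ("STABLE", "STABLE")]
    labels = [mapping[p] for p in pairs]
    if len(set(labels)) != len(labels):
        raise ValueError("group mapping must be injective over non-stable state pairs")


def classify(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    p_thresh: float = 0.05,
    fc_thresh: float = 0.6,
    mapping: Mapping[tuple[str, str], str] | None = None,
) -> pd.DataFrame:
    """Assign every miRNA a trajectory group from its two contrast results.

    The two tables must cover the same miRNA universe.  Returns a frame with
    columns mirna_id, state1, state2, group.
    """
    if mapping is None:
        mapping = DEFAULT_GROUP_MAPPING
    _validate_mapping(mapping)
    u1, u2 = set(de1["mirna_id"]), set(de2["mirna_id"])
    if u1 != u2:
        raise ValueError(
            f"contrast universes differ: {len(u1 - u2)} only in contrast 1, "
            f"{len(u2 - u1)} only in contrast 2"
        )
    d1 = de1.set_index("mirna_id")
    d2 = de2.set_index("mirna_id")
    rows = []
    for mid in de1["mirna_id"]:
        s1 = transition_state(d1.at[mid, "padj"], d1.at[mid, "log2fc"], p_thresh, fc_thresh)
        s2 = transition_state(d2.at[mid, "padj"], d2.at[mid, "log2fc"], p_thresh, fc_thresh)
        group = mapping.get((s1, s2), UNCLASSIFIED)
        if (s1, s2) == ("STABLE", "STABLE"):
            group = UNCLASSIFIED
        rows.append({"mirna_id": mid, "state1": s1, "state2": s2, "group": group})
    return pd.DataFrame(rows)


def top_ranked(de: pd.DataFrame, direction: str, n: int, p_thresh: float = 0.05) -> list[str]:
    """Top-n significant miRNAs of one sign, ordered by ascending padj, ties
    by |log2fc| descending then mirna_id ascending."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if direction not in {"up", "down"}:
        raise ValueError("direction must be 'up' or 'down'")
    sign = 1 if direction == "up" else -1
    sig = de[(de["padj"] < p_thresh) & (sign * de["log2fc"] > 0)].copy()
    sig["abs_lfc"] = sig["log2fc"].abs()
    sig = sig.sort_values(
        by=["padj", "abs_lfc", "mirna_id"], ascending=[True, False, True], kind="mergesort"
    )
    return list(sig["mirna_id"].head(n))


def doubling_time(n_start: float, n_end: float, hours: float = 48.0) -> float:
    """Population doubling time: hours * ln(2) / ln(n_end / n_start)."""
    if n_start <= 0 or n_end <= 0:
        raise ValueError("cell counts must be positive")
    if n_end <= n_start:
        raise ValueError("no growth between the two time points")
    return hours * math.log(2) / math.log(n_end / n_start)


def export_tables(
    calls: pd.DataFrame,
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    norm,
    outdir: str | Path,
) -> dict[str, Path]:
    """Write volcano, heatmap and group-membership TSVs.

    The heatmap holds per-miRNA z-scores of log2(mean normalized count + 1)
    across the cell types (a flat expression profile z-scores to all zeros).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}

    volcano = pd.concat([de1, de2], ignore_index=True)[
        ["mirna_id", "log2fc", "pvalue", "padj", "contrast"]
    ]
    paths["volcano"] = outdir / "volcano.tsv"
    volcano.to_csv(paths["volcano"], sep="\t", index=False)

    type_means = norm.type_means().loc[calls["mirna_id"]]
    logm = np.log2(type_means + 1.0)
    mu = logm.mean(axis=1)
    sd = logm.std(axis=1, ddof=0)
    z = logm.sub(mu, axis=0).div(sd.replace(0.0, np.nan), axis=0).fillna(0.0)
    paths["heatmap"] = outdir / "heatmap.tsv"
    z.to_csv(paths["heatmap"], sep="\t", index_label="mirna_id")

    paths["groups"] = outdir / "groups.tsv"
    calls.to_csv(paths["groups"], sep="\t", index=False)
    return paths
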