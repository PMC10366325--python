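"""Synthetic small-RNA data with planted structure.

Emulates the study design this package targets: three cell states
(hESC → self-renewing NSC → differentiating NSC) with 3/8/6 replicates,
negative-binomial counts over a log-normal abundance spectrum, planted
expression-trajectory groups at fixed log2 effect sizes, planted
cluster-dominance fractions (e.g. one cluster holding ~63% of reads in the
hESC-like state), and raw 75-cycle reads carrying a 3' adapter, sequencing
errors, contaminant reads and quality defects that exercise every filter.

What it does not emulate: ligation bias, UMIs, isomiR length/edit variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import AnnotatedMiRNA, ContaminantRef
from .diffexpr import CountMatrix

# NEB small-RNA kit 3' adapter (written in DNA alphabet, as it appears in reads)
DEFAULT_ADAPTER = "AGATCGGAAGAGCACACGTCT"

# Default planted log2 effect sizes per trajectory group: (transition 1, transition 2)
GROUP_EFFECTS: dict[str, tuple[float, float]] = {
    "G1": (+2.0, -2.0),
    "G2": (-2.0, +2.0),
    "G3": (+2.0, +2.0),
    "G4": (+2.0, 0.0),
    "G5": (-2.0, -2.0),
    "G6": (-2.0, 0.0),
    "G7": (0.0, +2.0),
    "G8": (0.0, -2.0),
}

PHRED_HIGH = 34
PHRED_LOW = 6
PHRED_END = 2  # below the end-trim threshold of 5


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Replicate counts default to the study design (3 hESC, 8 NSC, 6 Diff.NSC).
    ``dispersion`` is the NB alpha with variance = mu + alpha * mu^2.
    ``planted_groups`` maps a trajectory-group label to (number of miRNAs,
    (log2FC on transition 1, log2FC on transition 2)).
    ``planted_cluster_fraction`` maps (cell_type, cluster_id) to the target
    fraction of total expected reads held by that cluster's members.
    """

    n_mirnas: int = 347
    cell_types: tuple[str, ...] = ("hESC", "NSC", "DiffNSC")
    replicates: tuple[int, ...] = (3, 8, 6)
    baseline_mean: float = 500.0
    baseline_sigma: float = 1.0  # log-normal spread of baseline means
    dispersion: float = 0.05
    planted_groups: dict[str, tuple[int, tuple[float, float]]] = field(default_factory=dict)
    planted_cluster_fraction: dict[tuple[str, str], float] = field(default_factory=dict)
    cluster_members: dict[str, list[str]] = field(default_factory=dict)
    adapter: str = DEFAULT_ADAPTER
    read_error_rate: float = 0.001
    read_length: int = 75
    frac_contaminant: float = 0.10
    frac_low_quality: float = 0.05
    frac_no_adapter: float = 0.02
    frac_low_end: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if len(self.cell_types) != len(self.replicates):
            raise ValueError("cell_types and replicates length mismatch")
        if any(r < 0 for r in self.replicates):
            raise ValueError("replicate counts must be >= 0")
        if self.baseline_mean <= 0 or self.dispersion < 0:
            raise ValueError("baseline_mean must be > 0 and dispersion >= 0")
        n_planted = sum(n for n, _ in self.planted_groups.values())
        if n_planted > self.n_mirnas:
            raise ValueError("more planted miRNAs than n_mirnas")
        per_type: dict[str, float] = {}
        for (ct, _cid), frac in self.planted_cluster_fraction.items():
            if not 0 <= frac <= 1:
                raise ValueError("cluster fractions must be in [0, 1]")
            per_type[ct] = per_type.get(ct, 0.0) + frac
        for ct, tot in per_type.items():
            if tot > 1 + 1e-12:
                raise ValueError(f"cluster fractions for {ct} sum to {tot} > 1")

    def sample_ids(self) -> list[str]:
        return [
            f"{ct}_{r + 1}"
            for ct, n in zip(self.cell_types, self.replicates)
            for r in range(n)
        ]

    def sample_sheet(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{ct}_{r + 1}", "cell_type": ct, "replicate": r + 1}
            for ct, n in zip(self.cell_types, self.replicates)
            for r in range(n)
        ]
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery scoring."""

    group: pd.Series  # mirna_id -> planted group label ("stable" background)
    log2fc1: pd.Series
    log2fc2: pd.Series
    cluster_fractions: dict[tuple[str, str], float]
    mean_matrix: pd.DataFrame | None = None  # expected normalized mean per cell type

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {"group": self.group, "log2fc1": self.log2fc1, "log2fc2": self.log2fc2}
        )
        df.to_csv(path, sep="\t", index_label="mirna_id")


def _expected_means(
    spec: SimulationSpec, rng: np.random.Generator, mirna_ids: list[str]
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-miRNA expected mean for each cell type, with planting applied."""
    n = len(mirna_ids)
    baseline = spec.baseline_mean * np.exp(rng.normal(0.0, spec.baseline_sigma, size=n))
    group = np.array(["stable"] * n, dtype=object)
    lfc1 = np.zeros(n)
    lfc2 = np.zeros(n)
    pos = 0
    for label, (count, (e1, e2)) in spec.planted_groups.items():
        group[pos : pos + count] = label
        lfc1[pos : pos + count] = e1
        lfc2[pos : pos + count] = e2
        pos += count

    means = pd.DataFrame(index=mirna_ids, dtype=float)
    cum = np.zeros(n)
    for k, ct in enumerate(spec.cell_types):
        if k == 1:
            cum = cum + lfc1
        elif k == 2:
            cum = cum + lfc2
        means[ct] = baseline * np.power(2.0, cum)

    # plant cluster dominance: scale members to the target share of the type
    # total, rescale non-members so the total is preserved in expectation
    for (ct, cid), frac in spec.planted_cluster_fraction.items():
        if ct not in means.columns:
            raise ValueError(f"unknown cell type in cluster fractions: {ct}")
        members = spec.cluster_members.get(cid)
        if not members:
            raise ValueError(f"no members listed for planted cluster {cid}")
        member_mask = means.index.isin(members)
        if not member_mask.any():
            raise ValueError(f"cluster {cid} members not present in simulated miRNAs")
        total = means[ct].sum()
        m_sum = means.loc[member_mask, ct].sum()
        o_sum = total - m_sum
        if frac < 1 and o_sum <= 0:
            raise ValueError(f"cannot hold cluster {cid} below fraction 1 in {ct}")
        means.loc[member_mask, ct] *= frac * total / m_sum
        if o_sum > 0:
            means.loc[~member_mask, ct] *= (1 - frac) * total / o_sum

    truth = GroundTruth(
        group=pd.Series(group, index=mirna_ids),
        log2fc1=pd.Series(lfc1, index=mirna_ids),
        log2fc2=pd.Series(lfc2, index=mirna_ids),
        cluster_fractions=dict(spec.planted_cluster_fraction),
        mean_matrix=means,
    )
    return means, truth


def _nb_sample(rng: np.random.Generator, mu: np.ndarray, alpha: float) -> np.ndarray:
    """NB draw with variance mu + alpha*mu^2 (Poisson when alpha == 0)."""
    mu = np.asarray(mu, dtype=float)
    if alpha == 0:
        return rng.poisson(mu)
    r = 1.0 / alpha
    p = r / (r + mu)
    return rng.negative_binomial(r, p)


def simulate_counts(
    spec: SimulationSpec, mirna_ids: list[str] | None = None
) -> tuple[CountMatrix, GroundTruth]:
    """Draw an NB count matrix with the spec's planted structure."""
    rng = np.random.default_rng(spec.seed)
    if mirna_ids is None:
        mirna_ids = [f"mir-{i + 1:04d}" for i in range(spec.n_mirnas)]
    if len(mirna_ids) != spec.n_mirnas:
        raise ValueError("mirna_ids length must equal n_mirnas")
    means, truth = _expected_means(spec, rng, mirna_ids)

    cols = {}
    for ct, n_rep in zip(spec.cell_types, spec.replicates):
        mu = means[ct].to_numpy()
        for r in range(n_rep):
            cols[f"{ct}_{r + 1}"] = _nb_sample(rng, mu, spec.dispersion)
    counts = pd.DataFrame(cols, index=mirna_ids)
    cm = CountMatrix(counts=counts, sample_meta=spec.sample_sheet())
    return cm, truth


# --- raw-read simulation ---------------------------------------------------


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    bases = list(seq)
    hits = np.nonzero(rng.random(len(bases)) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != bases[i]]
        bases[i] = choices[rng.integers(len(choices))]
    return "".join(bases)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def simulate_reads(
    spec: SimulationSpec,
    mirnas: list[AnnotatedMiRNA],
    contaminants: list[ContaminantRef],
    n_reads: int,
    cell_type: str | None = None,
) -> tuple[list[tuple[str, str, str]], pd.DataFrame]:
    """Generate raw reads as (read_id, bases, quality) triples plus a source
    table recording each read's origin and planted defect.

    Reads are ``insert + adapter + random filler`` to ``read_length`` (75 by
    default, matching a 75-cycle run), written in DNA alphabet with Phred+33
    qualities.  Sampling weights over matures honour any planted cluster
    fraction for the given cell type.
    """
    if not spec.adapter:
        raise ValueError("adapter must be non-empty")
    rng = np.random.default_rng(spec.seed + 1)
    shortest = min(len(m.sequence) for m in mirnas)
    if spec.read_length < shortest + 1:
        raise ValueError("read_length shorter than shortest mature + 1 adapter base")

    # mature sampling weights, honouring a planted cluster fraction
    names = [m.mirna_id for m in mirnas]
    uniq = list(dict.fromkeys(names))
    weights = pd.Series(1.0, index=uniq)
    ct = cell_type or spec.cell_types[0]
    for (wct, cid), frac in spec.planted_cluster_fraction.items():
        if wct != ct:
            continue
        members = [m for m in spec.cluster_members.get(cid, []) if m in weights.index]
        if not members:
            continue
        mask = weights.index.isin(members)
        total = weights.sum()
        weights[mask] *= frac * total / weights[mask].sum()
        if (~mask).any():
            weights[~mask] *= (1 - frac) * total / weights[~mask].sum()
    probs = (weights / weights.sum()).to_numpy()
    seq_of = {m.mirna_id: m.sequence.replace("U", "T") for m in mirnas}

    reads: list[tuple[str, str, str]] = []
    sources = []
    for i in range(n_reads):
        rid = f"read_{i + 1:06d}"
        is_contaminant = rng.random() < spec.frac_contaminant and contaminants
        if is_contaminant:
            ref = contaminants[rng.integers(len(contaminants))]
            full = ref.sequence.replace("U", "T")
            ln = int(rng.integers(18, min(26, len(full)) + 1))
            start = int(rng.integers(0, len(full) - ln + 1))
            insert = full[start : start + ln]
            source_type, source_id = "contaminant", ref.ref_id
        else:
            source_id = str(weights.index[rng.choice(len(probs), p=probs)])
            insert = seq_of[source_id]
            source_type = "mirna"
        insert = _mutate(rng, insert, spec.read_error_rate)

        no_adapter = rng.random() < spec.frac_no_adapter
        if no_adapter:
            body = insert + _random_dna(rng, spec.read_length)
        else:
            body = insert + spec.adapter + _random_dna(rng, spec.read_length)
        bases = body[: spec.read_length]

        quals = np.full(len(bases), PHRED_HIGH, dtype=int)
        low_quality = rng.random() < spec.frac_low_quality
        if low_quality:
            # 40% of positions at low quality: violates the 85% >= Q10 rule
            n_low = int(np.ceil(0.4 * len(bases)))
            quals[rng.choice(len(bases), size=n_low, replace=False)] = PHRED_LOW
        low_end = rng.random() < spec.frac_low_end
        if low_end:
            k = int(rng.integers(1, 3))
            quals[:k] = PHRED_END
        qual_str = "".join(chr(q + 33) for q in quals)
        reads.append((rid, bases, qual_str))
        sources.append(
            {
                "read_id": rid,
                "source_type": source_type,
                "source_id": source_id,
                "no_adapter": no_adapter,
                "low_quality": low_quality,
                "low_end": low_end,
            }
        )
    return reads, pd.DataFrame(sources).set_index("read_id")


def write_fastq(reads: list[tuple[str, str, str]], path: str | Path) -> None:
    """Write (id, bases, qual) triples as Phred+33 FASTQ."""
    with open(path, "w") as fh:
        for rid, bases, qual in reads:
            fh.write(f"@{rid}\n{bases}\n+\n{qual}\n")
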