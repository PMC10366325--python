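"""miRNA reference model: mature sequences, seeds, genomic clusters, seed families.

A mature miRNA is identified by its name (e.g. ``hsa-miR-92a-3p``) and its
16–27 nt RNA sequence.  The *seed* — nucleotides 2–8 of the mature sequence —
is the principal determinant of target recognition and the basis for family
assignment: a miRNA family is the set of matures sharing an identical seed.
A miRNA *cluster* is a group of miRNA genes co-located on the same chromosome
and strand within a short genomic window, typically co-transcribed as one
polycistronic unit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO

MIN_MATURE_LEN = 16
MAX_MATURE_LEN = 27
SEED_START = 2  # 1-based, inclusive
SEED_END = 8
RNA_ALPHABET = frozenset("ACGU")
NCRNA_CLASSES = frozenset({"rRNA", "tRNA", "snoRNA", "snRNA", "YRNA"})


def _normalize_rna(seq: str) -> str:
    return seq.strip().upper().replace("T", "U")


def extract_seed(sequence: str) -> str:
    """Return nucleotides 2–8 (1-based, inclusive) of a mature sequence."""
    if len(sequence) < SEED_END:
        raise ValueError(f"sequence shorter than seed window: {sequence!r}")
    return sequence[SEED_START - 1 : SEED_END]


@dataclass(frozen=True)
class AnnotatedMiRNA:
    """A mature miRNA with its seed and (optionally) a genomic locus.

    Coordinates are 1-based inclusive, GFF3 convention.
    """

    mirna_id: str
    sequence: str
    seed: str = ""
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    cluster_id: str | None = None
    family_id: str | None = None

    def __post_init__(self):
        seq = _normalize_rna(self.sequence)
        object.__setattr__(self, "sequence", seq)
        if not (MIN_MATURE_LEN <= len(seq) <= MAX_MATURE_LEN):
            raise ValueError(
                f"{self.mirna_id}: mature length {len(seq)} outside "
                f"[{MIN_MATURE_LEN}, {MAX_MATURE_LEN}]"
            )
        bad = set(seq) - RNA_ALPHABET
        if bad:
            raise ValueError(f"{self.mirna_id}: non-RNA characters {sorted(bad)}")
        object.__setattr__(self, "seed", extract_seed(seq))
        if self.start is not None and self.end is not None and self.start > self.end:
            raise ValueError(f"{self.mirna_id}: start > end")
        if self.strand is not None and self.strand not in {"+", "-"}:
            raise ValueError(f"{self.mirna_id}: strand must be + or -")


@dataclass(frozen=True)
class ContaminantRef:
    """A non-miRNA small-RNA reference used for contaminant exclusion."""

    ref_id: str
    ncrna_class: str
    sequence: str

    def __post_init__(self):
        if self.ncrna_class not in NCRNA_CLASSES:
            raise ValueError(
                f"{self.ref_id}: class {self.ncrna_class!r} not in {sorted(NCRNA_CLASSES)}"
            )
        object.__setattr__(self, "sequence", _normalize_rna(self.sequence))


@dataclass
class ClusterTable:
    """cluster_id → ordered member mirna_ids, plus the derivation parameters."""

    members: dict[str, list[str]] = field(default_factory=dict)
    max_gap_bp: int | None = None
    same_strand: bool = True

    def cluster_of(self) -> dict[str, str]:
        """Invert to mirna_id → cluster_id."""
        out: dict[str, str] = {}
        for cid, mids in self.members.items():
            for m in mids:
                out[m] = cid
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"cluster_id": cid, "mirna_id": m}
            for cid, mids in self.members.items()
            for m in mids
        ]
        return pd.DataFrame(rows, columns=["cluster_id", "mirna_id"])

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ClusterTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        table = cls()
        for cid, grp in df.groupby("cluster_id", sort=False):
            table.members[cid] = list(grp["mirna_id"])
        return table


def _parse_gff3_attributes(attr_field: str) -> dict[str, str]:
    out = {}
    for part in attr_field.strip().split(";"):
        if not part:
            continue
        key, _, val = part.partition("=")
        out[key.strip()] = val.strip()
    return out


def read_gff3_loci(path: str | Path) -> list[dict]:
    """Read miRNA locus records from a GFF3 file.

    Returns dicts with name, chrom, start, end, strand.  Raises on malformed
    lines, naming the line number.
    """
    loci = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: expected 9 fields")
            chrom, _source, _type, start, end, _score, strand, _phase, attrs = fields
            try:
                start_i, end_i = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}: malformed GFF3 line {lineno}: {exc}") from exc
            parsed = _parse_gff3_attributes(attrs)
            name = parsed.get("Name") or parsed.get("ID")
            if name is None:
                raise ValueError(f"{path}: GFF3 line {lineno} lacks ID/Name attribute")
            loci.append(
                {"name": name, "chrom": chrom, "start": start_i, "end": end_i, "strand": strand}
            )
    return loci


def load_reference(
    mature_fasta: str | Path, genomic_gff: str | Path | None = None
) -> list[AnnotatedMiRNA]:
    """Load mature miRNAs from FASTA, joining loci from a GFF3 by Name/ID.

    DNA-alphabet FASTA (T) is transparently converted to RNA (U).  Matures
    shorter than 16 nt or longer than 27 nt are rejected.  A mature without a
    locus is retained with a warning (it simply cannot cluster).  A mature
    name mapping to several loci yields one record per locus.
    """
    loci_by_name: dict[str, list[dict]] = {}
    if genomic_gff is not None:
        for loc in read_gff3_loci(genomic_gff):
            loci_by_name.setdefault(loc["name"], []).append(loc)

    mirnas: list[AnnotatedMiRNA] = []
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        name = rec.id
        base = AnnotatedMiRNA(mirna_id=name, sequence=str(rec.seq))
        matched = loci_by_name.get(name)
        if genomic_gff is not None and not matched:
            warnings.warn(f"mature {name} has no locus in {genomic_gff}; retained unclustered")
        if matched:
            for loc in matched:
                mirnas.append(
                    replace(
                        base,
                        chrom=loc["chrom"],
                        start=loc["start"],
                        end=loc["end"],
                        strand=loc["strand"],
                    )
                )
        else:
            mirnas.append(base)
    return assign_families_inplace(mirnas)


def load_contaminants(fasta: str | Path) -> list[ContaminantRef]:
    """Read contaminant references; ncRNA class from a ``class=`` tag in the
    description, else from the id prefix before the first '-'."""
    refs = []
    for rec in SeqIO.parse(str(fasta), "fasta"):
        cls = None
        for tok in rec.description.split():
            if tok.startswith("class="):
                cls = tok.split("=", 1)[1]
        if cls is None:
            cls = rec.id.split("-")[0]
        refs.append(ContaminantRef(ref_id=rec.id, ncrna_class=cls, sequence=str(rec.seq)))
    return refs


def derive_clusters(
    mirnas: Iterable[AnnotatedMiRNA], max_gap_bp: int = 10_000, same_strand: bool = True
) -> ClusterTable:
    """Single-linkage grouping of loci within ``max_gap_bp`` on one chromosome
    (and strand, if ``same_strand``).

    The gap between two loci is ``next.start - prev.end``.  Singletons are
    excluded.  Cluster ids are ``cluster:<leftmost member name>``.  A mature
    whose loci fall into different clusters is kept only in the cluster of its
    leftmost locus (with a warning), so each mature belongs to at most one
    cluster.
    """
    located = [m for m in mirnas if m.chrom is not None]
    keyfn = (lambda m: (m.chrom, m.strand)) if same_strand else (lambda m: (m.chrom,))
    groups: dict[tuple, list[AnnotatedMiRNA]] = {}
    for m in located:
        groups.setdefault(keyfn(m), []).append(m)

    raw_clusters: list[list[AnnotatedMiRNA]] = []
    for _, members in groups.items():
        members.sort(key=lambda m: (m.start, m.end, m.mirna_id))
        run = [members[0]]
        for m in members[1:]:
            if m.start - run[-1].end <= max_gap_bp:
                run.append(m)
            else:
                raw_clusters.append(run)
                run = [m]
        raw_clusters.append(run)

    table = ClusterTable(max_gap_bp=max_gap_bp, same_strand=same_strand)
    seen: dict[str, str] = {}
    # leftmost-first ordering makes multi-locus resolution deterministic
    raw_clusters.sort(key=lambda c: (c[0].chrom, c[0].start, c[0].mirna_id))
    for run in raw_clusters:
        if len(run) < 2:
            continue
        cid = f"cluster:{run[0].mirna_id}"
        kept = []
        for m in run:
            if m.mirna_id in seen:
                warnings.warn(
                    f"{m.mirna_id} has loci in multiple clusters; kept in {seen[m.mirna_id]}"
                )
                continue
            seen[m.mirna_id] = cid
            kept.append(m.mirna_id)
        if len(kept) >= 2:
            table.members[cid] = kept
    return table


def assign_families(mirnas: Iterable[AnnotatedMiRNA]) -> dict[str, list[str]]:
    """Group matures by identical seed.

    family_id is ``seed:<lexicographically smallest member name>``; each
    mature appears once even if it has several locus records.
    """
    by_seed: dict[str, set[str]] = {}
    for m in mirnas:
        by_seed.setdefault(m.seed, set()).add(m.mirna_id)
    families: dict[str, list[str]] = {}
    for _, names in by_seed.items():
        ordered = sorted(names)
        families[f"seed:{ordered[0]}"] = ordered
    return families


def assign_families_inplace(mirnas: list[AnnotatedMiRNA]) -> list[AnnotatedMiRNA]:
    """Set family_id on each record; returns new records (frozen dataclass)."""
    families = assign_families(mirnas)
    fam_of = {m: fid for fid, members in families.items() for m in members}
    return [replace(m, family_id=fam_of[m.mirna_id]) for m in mirnas]


def family_table(mirnas: Iterable[AnnotatedMiRNA]) -> pd.DataFrame:
    rows = [
        {"family_id": fid, "mirna_id": m}
        for fid, members in assign_families(mirnas).items()
        for m in members
    ]
    return pd.DataFrame(rows, columns=["family_id", "mirna_id"])


def _longest_common_substring(a: str, b: str) -> int:
    best = 0
    for i in range(len(a)):
        for j in range(i + best + 1, len(a) + 1):
            if a[i:j] in b:
                best = j - i
            else:
                break
    return best


def seed_similarity(seed_a: str, seed_b: str) -> tuple[str, int]:
    """Compare two 7-mer seeds.

    Score is the length of the longest common substring; category is
    ``identical`` (equal), ``similar`` (score >= 6), else ``dissimilar``.
    """
    if len(seed_a) != 7 or len(seed_b) != 7:
        raise ValueError("seeds must be exactly 7 nt")
    if seed_a == seed_b:
        return "identical", 7
    score = _longest_common_substring(seed_a, seed_b)
    return ("similar" if score >= 6 else "dissimilar"), score


# --- packaged reference fixture -------------------------------------------

def packaged_reference_paths() -> Mapping[str, Path]:
    """Paths of the packaged mature/locus/contaminant fixture files.

    Mature sequences follow the public miRBase v22.1 catalogue; locus
    coordinates are approximate hg38 positions that preserve the co-location
    of the miR-302-367, miR-17-92, miR-106a-363 and miR-106b-25 clusters.
    The contaminant FASTA is synthetic.  All three are user-replaceable.
    """
    data = resources.files("mirflow") / "data"
    return {
        "mature": Path(str(data / "mature_mirbase_v22_1.fa")),
        "gff": Path(str(data / "loci_hg38.gff3")),
        "contaminants": Path(str(data / "contaminants_synthetic.fa")),
    }


def load_packaged_reference() -> tuple[list[AnnotatedMiRNA], list[ContaminantRef]]:
    paths = packaged_reference_paths()
    return load_reference(paths["mature"], paths["gff"]), load_contaminants(
        paths["contaminants"]
    )
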