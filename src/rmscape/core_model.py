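"""Domain types, genome I/O and the gene-rank distance calculus.

Genomes are ordered, strand-aware collections of protein-coding genes over
one or more replicons (chromosome, plasmid or phage).  All neighbourhood
logic downstream of this module operates on *gene ranks*: the 0-based
position of a gene in the coordinate-sorted gene order of its replicon.
"N genes apart" always means a rank offset of N, so adjacent genes are one
apart.  Strand is never used in distance computations.

Coordinates are stored 1-based inclusive (GenBank convention).  Partial
CDS, CDS without a stop codon and CDS with an internal stop are rejected
at load time and accounted for in a :class:`LoadReport`.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

REPLICON_KINDS = ("chromosome", "plasmid", "phage")


class FormatError(ValueError):
    """Raised when an input file does not parse under the declared format."""


@dataclass
class Gene:
    """A protein-coding gene anchored to a replicon.

    ``rank`` is the 0-based index of the gene in the coordinate-sorted
    gene order of its replicon; ``start``/``end`` are 1-based inclusive
    base-pair coordinates with ``start <= end`` irrespective of strand.
    """

    gene_id: str
    replicon_id: str
    rank: int
    start: int
    end: int
    strand: str
    protein_seq: str
    dna_seq: str | None = None

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"{self.gene_id}: end < start")
        if "*" in self.protein_seq:
            raise ValueError(f"{self.gene_id}: internal stop in protein_seq")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-'")


@dataclass
class Replicon:
    replicon_id: str
    kind: str
    length_bp: int
    circular: bool
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.kind not in REPLICON_KINDS:
            raise ValueError(f"unknown replicon kind {self.kind!r}")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_at(self, rank: int) -> Gene:
        return self.genes[rank]

    def validate(self) -> None:
        for i, g in enumerate(self.genes):
            if g.rank != i:
                raise ValueError(f"{self.replicon_id}: ranks not consecutive at {i}")
            if g.end > self.length_bp:
                raise ValueError(f"{g.gene_id}: coordinates exceed replicon length")


@dataclass
class Genome:
    genome_id: str
    clade: str
    replicons: list[Replicon] = field(default_factory=list)
    load_report: "LoadReport | None" = None

    @property
    def size_mb(self) -> float:
        return sum(r.length_bp for r in self.replicons) / 1e6

    def genes(self) -> Iterator[Gene]:
        for rep in self.replicons:
            yield from rep.genes

    def replicon(self, replicon_id: str) -> Replicon:
        for rep in self.replicons:
            if rep.replicon_id == replicon_id:
                return rep
        raise KeyError(replicon_id)

    def gene_index(self) -> dict[str, Gene]:
        return {g.gene_id: g for g in self.genes()}


@dataclass
class LoadReport:
    """Accounting of CDS retained/dropped while loading one genome."""

    retained: int = 0
    dropped_partial: int = 0
    dropped_internal_stop: int = 0
    dropped_no_stop_codon: int = 0
    dropped_untranslatable: int = 0

    @property
    def dropped(self) -> int:
        return (self.dropped_partial + self.dropped_internal_stop
                + self.dropped_no_stop_codon + self.dropped_untranslatable)

    @property
    def total(self) -> int:
        return self.retained + self.dropped


@dataclass
class TruthTable:
    """Planted ground truth keyed by gene_id (synthetic datasets only)."""

    roles: dict[str, dict] = field(default_factory=dict)
    systems: list[dict] = field(default_factory=list)
    solitary: list[str] = field(default_factory=list)
    ambiguous: list[str] = field(default_factory=list)
    mge_members: dict[str, str] = field(default_factory=dict)
    families: dict[str, str] = field(default_factory=dict)
    core_genes: list[str] = field(default_factory=list)
    extra: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "roles": self.roles, "systems": self.systems,
            "solitary": self.solitary, "ambiguous": self.ambiguous,
            "mge_members": self.mge_members, "families": self.families,
            "core_genes": self.core_genes, "extra": self.extra,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        d = json.loads(Path(path).read_text())
        return cls(**d)


# ---------------------------------------------------------------------------
# distance calculus


def gene_distance(a: Gene, b: Gene, replicon: Replicon) -> int:
    """Rank offset between two genes of the same replicon.

    Linear replicons use ``|rank(a) - rank(b)|``; circular replicons take
    the shorter of the two arcs.  Symmetric; zero iff the two genes are the
    same gene.
    """
    if a.replicon_id != b.replicon_id or a.replicon_id != replicon.replicon_id:
        raise ValueError("gene_distance undefined across replicons")
    return rank_distance(a.rank, b.rank, replicon.n_genes, replicon.circular)


def rank_distance(i: int, j: int, n_genes: int, circular: bool) -> int:
    d = abs(i - j)
    if circular and n_genes:
        d = min(d, n_genes - d)
    return d


def neighborhood_ranks(rank: int, width: int, n_genes: int, circular: bool) -> list[int]:
    """Ranks within ``width`` of ``rank`` (excluding it), wrapping if circular."""
    out = set()
    for off in range(1, width + 1):
        for s in (-1, 1):
            r = rank + s * off
            if circular:
                out.add(r % n_genes)
            elif 0 <= r < n_genes:
                out.add(r)
    out.discard(rank)
    return sorted(out)


# ---------------------------------------------------------------------------
# GenBank / GFF3 I/O

_KIND_KEY = "replicon_kind"


def _record_kind(record: SeqRecord) -> str:
    for feat in record.features:
        if feat.type == "source":
            if "plasmid" in feat.qualifiers:
                return "plasmid"
            for note in feat.qualifiers.get("note", []):
                for tok in note.replace(";", " ").split():
                    if tok.startswith(_KIND_KEY + "="):
                        return tok.split("=", 1)[1]
    desc = (record.description or "").lower()
    if "plasmid" in desc:
        return "plasmid"
    if "phage" in desc:
        return "phage"
    return "chromosome"


def _is_partial(feat: SeqFeature) -> bool:
    if "partial" in feat.qualifiers:
        return True
    loc = str(feat.location)
    return "<" in loc or ">" in loc


def read_genbank(path: str | Path, genome_id: str | None = None,
                 clade: str = "") -> Genome:
    """Load a (possibly multi-record) GenBank flat file as one Genome."""
    path = Path(path)
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # pragma: no cover - biopython error text varies
        raise FormatError(f"{path}: not parseable as GenBank: {exc}") from exc
    if not records:
        raise FormatError(f"{path}: no GenBank records found")
    report = LoadReport()
    replicons = []
    for record in records:
        circular = record.annotations.get("topology", "linear") == "circular"
        rep = Replicon(record.id, _record_kind(record), len(record.seq), circular)
        genes = []
        for feat in record.features:
            if feat.type != "CDS":
                continue
            gid = feat.qualifiers.get("locus_tag", feat.qualifiers.get("gene", ["?"]))[0]
            if _is_partial(feat) or "pseudo" in feat.qualifiers:
                report.dropped_partial += 1
                continue
            dna = str(feat.extract(record.seq))
            prot = feat.qualifiers.get("translation", [None])[0]
            if prot is None:
                if len(dna) % 3:
                    report.dropped_untranslatable += 1
                    continue
                prot = str(Seq(dna).translate())
                if prot.endswith("*"):
                    prot = prot[:-1]
            if "*" in prot:
                report.dropped_internal_stop += 1
                continue
            if len(dna) % 3 == 0 and len(dna) >= 3:
                aa = str(Seq(dna[-3:]).translate())
                if aa != "*":
                    report.dropped_no_stop_codon += 1
                    continue
            genes.append(Gene(
                gene_id=gid, replicon_id=record.id, rank=0,
                start=int(feat.location.start) + 1, end=int(feat.location.end),
                strand="+" if feat.location.strand != -1 else "-",
                protein_seq=prot, dna_seq=dna))
            report.retained += 1
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(genes):
            g.rank = i
        rep.genes = genes
        if not genes:
            warnings.warn(f"{record.id}: no genes retained", stacklevel=2)
        replicons.append(rep)
    genome = Genome(genome_id or path.stem, clade, replicons, report)
    return genome


def write_genbank(genome: Genome, path: str | Path,
                  replicon_seqs: dict[str, str]) -> None:
    """Write a Genome as a multi-record GenBank flat file.

    ``replicon_seqs`` supplies the full nucleotide sequence per replicon.
    """
    records = []
    for rep in genome.replicons:
        seq = Seq(replicon_seqs[rep.replicon_id])
        record = SeqRecord(seq, id=rep.replicon_id, name=rep.replicon_id[:16],
                           description=f"{genome.genome_id} {rep.kind}")
        record.annotations["molecule_type"] = "DNA"
        record.annotations["topology"] = "circular" if rep.circular else "linear"
        src = SeqFeature(SimpleLocation(0, rep.length_bp), type="source")
        src.qualifiers["note"] = [f"{_KIND_KEY}={rep.kind}"]
        record.features.append(src)
        for g in rep.genes:
            loc = SimpleLocation(g.start - 1, g.end, 1 if g.strand == "+" else -1)
            feat = SeqFeature(loc, type="CDS")
            feat.qualifiers["locus_tag"] = [g.gene_id]
            feat.qualifiers["translation"] = [g.protein_seq]
            record.features.append(feat)
        records.append(record)
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "genbank")


def write_gff3(genome: Genome, gff_path: str | Path, fasta_path: str | Path,
               replicon_seqs: dict[str, str]) -> None:
    """Write a Genome as a GFF3 file plus its companion nucleotide FASTA."""
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rep in genome.replicons:
            fh.write(f"##sequence-region {rep.replicon_id} 1 {rep.length_bp}\n")
            circ = "true" if rep.circular else "false"
            fh.write("\t".join([
                rep.replicon_id, "rmscape", "region", "1", str(rep.length_bp),
                ".", "+", ".",
                f"ID={rep.replicon_id};{_KIND_KEY}={rep.kind};Is_circular={circ}",
            ]) + "\n")
            for g in rep.genes:
                attrs = f"ID={g.gene_id};translation={g.protein_seq}"
                fh.write("\t".join([
                    rep.replicon_id, "rmscape", "CDS", str(g.start), str(g.end),
                    ".", g.strand, "0", attrs]) + "\n")
    records = [SeqRecord(Seq(replicon_seqs[r.replicon_id]), id=r.replicon_id,
                         description="") for r in genome.replicons]
    SeqIO.write(records, str(fasta_path), "fasta")


def read_gff3(gff_path: str | Path, fasta_path: str | Path,
              genome_id: str | None = None, clade: str = "") -> Genome:
    """Load a GFF3 + nucleotide FASTA pair as one Genome."""
    gff_path = Path(gff_path)
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    report = LoadReport()
    replicons: dict[str, Replicon] = {}
    pending: dict[str, list[Gene]] = {}
    for lineno, line in enumerate(gff_path.read_text().splitlines(), 1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise FormatError(f"{gff_path}:{lineno}: expected 9 columns")
        seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts
        attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if ftype == "region":
            circular = attr.get("Is_circular", "false") == "true"
            if seqid not in seqs:
                raise FormatError(f"{gff_path}:{lineno}: {seqid} missing from FASTA")
            replicons[seqid] = Replicon(seqid, attr.get(_KIND_KEY, "chromosome"),
                                        len(seqs[seqid]), circular)
            pending.setdefault(seqid, [])
        elif ftype == "CDS":
            s, e = int(start), int(end)
            dna = seqs[seqid][s - 1:e]
            if strand == "-":
                dna = str(Seq(dna).reverse_complement())
            prot = attr.get("translation")
            if prot is None:
                if len(dna) % 3:
                    report.dropped_untranslatable += 1
                    continue
                prot = str(Seq(dna).translate()).rstrip("*")
            if "*" in prot:
                report.dropped_internal_stop += 1
                continue
            pending.setdefault(seqid, []).append(Gene(
                attr.get("ID", f"gene{lineno}"), seqid, 0, s, e, strand, prot, dna))
            report.retained += 1
    out = []
    for seqid, rep in replicons.items():
        genes = sorted(pending.get(seqid, []), key=lambda g: (g.start, g.end, g.gene_id))
        for i, g in enumerate(genes):
            g.rank = i
        rep.genes = genes
        out.append(rep)
    return Genome(genome_id or gff_path.stem, clade, out, report)


def read_annotated_genome(path: str | Path, format: str = "genbank", *,
                          fasta: str | Path | None = None,
                          genome_id: str | None = None, clade: str = "") -> Genome:
    """Load one annotated genome in GenBank or GFF3+FASTA format."""
    if format == "genbank":
        return read_genbank(path, genome_id, clade)
    if format in ("gff3", "gff3+fasta"):
        if fasta is None:
            fasta = Path(path).with_suffix(".fna")
        return read_gff3(path, fasta, genome_id, clade)
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# report writing


def gene_table(genome: Genome) -> pd.DataFrame:
    """Flat per-gene table (coordinates 1-based inclusive)."""
    rows = [{
        "genome_id": genome.genome_id, "replicon_id": g.replicon_id,
        "gene_id": g.gene_id, "rank": g.rank, "start": g.start, "end": g.end,
        "strand": g.strand, "protein_seq": g.protein_seq,
    } for g in genome.genes()]
    return pd.DataFrame(rows, columns=["genome_id", "replicon_id", "gene_id",
                                       "rank", "start", "end", "strand",
                                       "protein_seq"])


def export_report(tables: dict[str, pd.DataFrame], out_dir: str | Path,
                  config: dict | None = None) -> dict:
    """Write named result tables as deterministic TSVs plus a JSON manifest.

    Column order is taken from each DataFrame; rows are written as-is (the
    producing modules emit deterministically ordered tables).  The manifest
    records per-table row counts and a hash of the configuration.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg_hash = hashlib.sha256(
        json.dumps(config or {}, sort_keys=True, default=str).encode()).hexdigest()
    manifest = {"config_hash": cfg_hash, "tables": {}}
    for name in sorted(tables):
        df = tables[name]
        dest = out_dir / f"{name}.tsv"
        df.to_csv(dest, sep="\t", index=False, lineterminator="\n",
                  float_format="%.10g")
        manifest["tables"][name] = {"rows": int(len(df)), "path": dest.name}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                      sort_keys=True))
    return manifest
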