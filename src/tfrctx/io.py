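"""Reading and writing annotations, hit tables and interval outputs.

GenBank parsing goes through Biopython, GFF3 through gffutils; everything
is normalised into the :class:`~tfrctx.model.AnnotationBundle` model with
1-based inclusive coordinates.
"""
from __future__ import annotations

import hashlib
import textwrap
import warnings
from pathlib import Path
from typing import Iterable, Optional, Sequence

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq, UndefinedSequenceError
from Bio.SeqFeature import FeatureLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .model import AnnotationBundle, DomainHit, GeneRecord, Replicon

PFAM_TETR = "PF00440"


def file_checksum(path: str | Path) -> str:
    """sha256 of a file, recorded for provenance (annotation releases of
    public genomes differ; the checksum pins exactly what was analysed)."""
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


# ---------------------------------------------------------------------------
# annotation readers
# ---------------------------------------------------------------------------

def _feature_to_gene(feat, replicon_id: str) -> Optional[GeneRecord]:
    locus = feat.qualifiers.get("locus_tag", [None])[0]
    if not locus:
        return None
    product = feat.qualifiers.get("product", [""])[0]
    # compound (join) locations collapse to their extremes
    start = int(feat.location.start) + 1
    end = int(feat.location.end)
    strand = "-" if feat.location.strand == -1 else "+"
    kind = "CDS" if feat.type == "CDS" else "other"
    return GeneRecord(replicon_id, locus, strand, start, end, kind, product)


def read_genbank(path: str | Path, *, cds_only: bool = True) -> AnnotationBundle:
    """Parse a GenBank flat file into an annotation bundle.

    One replicon per record; each CDS with a ``locus_tag`` qualifier becomes
    a gene. Features lacking a locus tag are skipped with a warning. With
    ``cds_only=False`` every feature kind except ``source`` is admitted.
    """
    path = Path(path)
    replicons = []
    skipped = 0
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise ValueError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no GenBank records found in {path}")
    for rec in records:
        genes = []
        wanted = ("CDS",) if cds_only else None
        for feat in rec.features:
            if feat.type == "source":
                continue
            if wanted is not None and feat.type not in wanted:
                continue
            gene = _feature_to_gene(feat, rec.id)
            if gene is None:
                skipped += 1
                continue
            genes.append(gene)
        try:
            seq = str(rec.seq).upper()
        except UndefinedSequenceError:
            seq = None
        length = len(rec) if len(rec) else (max(g.end for g in genes) if genes else 1)
        topology = rec.annotations.get("topology", "linear")
        if topology not in ("linear", "circular"):
            topology = "linear"
        replicons.append(Replicon(rec.id, length, topology, seq, genes))
    if skipped:
        warnings.warn(f"{path}: skipped {skipped} feature(s) lacking a locus_tag")
    return AnnotationBundle(replicons, str(path), file_checksum(path))


def read_gff3(
    gff_path: str | Path,
    fasta_path: Optional[str | Path] = None,
    *,
    cds_only: bool = True,
) -> AnnotationBundle:
    """Parse GFF3 (optionally with a genome FASTA) into an annotation bundle.

    CDS features are preferred; when the file carries only ``gene`` features
    those are used instead. Locus tags come from the ``locus_tag`` attribute,
    falling back to ``ID``.
    """
    gff_path = Path(gff_path)
    try:
        db = gffutils.create_db(
            str(gff_path),
            dbfn=":memory:",
            force=True,
            keep_order=True,
            merge_strategy="create_unique",
        )
    except gffutils.exceptions.EmptyInputError:
        warnings.warn(f"{gff_path}: no recognized gene features; empty bundle")
        return AnnotationBundle([], str(gff_path), file_checksum(gff_path))
    featuretypes = set(db.featuretypes())
    if "CDS" in featuretypes:
        kinds = ["CDS"]
    elif "gene" in featuretypes:
        kinds = ["gene"]
    elif not cds_only and featuretypes:
        kinds = sorted(featuretypes)
    else:
        kinds = []

    sequences: dict[str, str] = {}
    lengths: dict[str, int] = {}
    topologies: dict[str, str] = {}
    if fasta_path is not None:
        for rec in SeqIO.parse(str(fasta_path), "fasta"):
            sequences[rec.id] = str(rec.seq).upper()
            lengths[rec.id] = len(rec.seq)

    # ##sequence-region directives give lengths when no FASTA is supplied
    for directive in db.directives:
        parts = directive.split()
        if parts and parts[0] == "sequence-region" and len(parts) >= 4:
            lengths.setdefault(parts[1], int(parts[3]))

    genes_by_seqid: dict[str, list[GeneRecord]] = {}
    for kind in kinds:
        for feat in db.features_of_type(kind):
            locus = feat.attributes.get("locus_tag", feat.attributes.get("ID", [None]))[0]
            if not locus:
                warnings.warn(f"{gff_path}: {kind} feature without locus_tag/ID skipped")
                continue
            product = feat.attributes.get("product", [""])[0]
            genes_by_seqid.setdefault(feat.seqid, []).append(
                GeneRecord(
                    feat.seqid,
                    locus,
                    "-" if feat.strand == "-" else "+",
                    feat.start,
                    feat.end,
                    "CDS" if kind == "CDS" else "other",
                    product,
                )
            )
    if not genes_by_seqid:
        warnings.warn(f"{gff_path}: no recognized gene features; empty bundle")

    if fasta_path is not None:
        missing = sorted(set(genes_by_seqid) - set(sequences))
        if missing:
            raise ValueError(
                f"seqids in {gff_path} absent from {fasta_path}: {', '.join(missing)}"
            )

    seqids = sorted(set(genes_by_seqid) | set(sequences))
    replicons = []
    for seqid in seqids:
        genes = genes_by_seqid.get(seqid, [])
        length = lengths.get(seqid) or (max(g.end for g in genes) if genes else 1)
        replicons.append(
            Replicon(
                seqid,
                length,
                topologies.get(seqid, "linear"),
                sequences.get(seqid),
                genes,
            )
        )
    return AnnotationBundle(replicons, str(gff_path), file_checksum(gff_path))


# ---------------------------------------------------------------------------
# regulator lists and domain-hit tables
# ---------------------------------------------------------------------------

def read_locus_list(path: str | Path) -> set[str]:
    """Plain locus-tag list, one per line; '#' starts a comment."""
    tags = set()
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if line:
            tags.add(line)
    return tags


def read_domain_hits(path: str | Path) -> list[DomainHit]:
    """TSV with header locus_tag/domain_accession/domain_name/score/evalue."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"locus_tag", "domain_accession"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: domain-hit table needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    hits = []
    for row in df.itertuples(index=False):
        score = getattr(row, "score", None)
        evalue = getattr(row, "evalue", None)
        hits.append(
            DomainHit(
                locus_tag=row.locus_tag,
                domain_accession=row.domain_accession,
                domain_name=str(getattr(row, "domain_name", "") or ""),
                score=float(score) if score not in (None, "") and score == score else None,
                evalue=float(evalue) if evalue not in (None, "") and evalue == evalue else None,
            )
        )
    return hits


def select_tfrs(
    hits: Iterable[DomainHit],
    accession: str = PFAM_TETR,
    min_score: float = 25.0,
) -> set[str]:
    """Locus tags with at least one hit to ``accession`` scoring >= min_score.

    The TetR-family DNA-binding domain is Pfam PF00440 (TetR_N); any hit
    table restricted by this filter defines the regulator set under study.
    """
    hits = list(hits)
    if not hits:
        warnings.warn("empty domain-hit table: no regulators selected")
        return set()
    selected = set()
    for h in hits:
        if h.domain_accession == accession and (h.score is None or h.score >= min_score):
            selected.add(h.locus_tag)
    return selected


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def write_gene_table(bundle: AnnotationBundle, path: str | Path) -> None:
    rows = [
        {
            "replicon": g.replicon_id,
            "locus_tag": g.locus_tag,
            "strand": g.strand,
            "start": g.start,
            "end": g.end,
            "product": g.product_text,
        }
        for g in bundle.all_genes()
    ]
    pd.DataFrame(rows, columns=["replicon", "locus_tag", "strand", "start", "end", "product"]).to_csv(
        path, sep="\t", index=False
    )


def read_gene_table(path: str | Path) -> AnnotationBundle:
    df = pd.read_csv(path, sep="\t", dtype={"start": int, "end": int}, keep_default_na=False)
    replicons = []
    for rid, sub in df.groupby("replicon", sort=True):
        genes = [
            GeneRecord(rid, r.locus_tag, r.strand, int(r.start), int(r.end), "CDS", str(r.product))
            for r in sub.itertuples(index=False)
        ]
        replicons.append(Replicon(rid, max(g.end for g in genes), "linear", None, genes))
    return AnnotationBundle(replicons, str(path), file_checksum(path))


def write_genbank(bundle: AnnotationBundle, path: str | Path) -> None:
    """Emit the bundle as a GenBank flat file (fixed date for determinism)."""
    records = []
    for rep in bundle.replicons:
        if rep.sequence is None:
            raise ValueError(f"{rep.replicon_id}: cannot write GenBank without sequence")
        rec = SeqRecord(
            Seq(rep.sequence),
            id=rep.replicon_id,
            name=rep.replicon_id[:16],
            description="synthetic replicon",
        )
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = rep.topology
        rec.annotations["date"] = "01-JAN-2000"
        rec.annotations["data_file_division"] = "BCT"
        for g in rep.genes:
            feat = SeqFeature(
                FeatureLocation(g.start - 1, g.end, strand=-1 if g.strand == "-" else 1),
                type="CDS",
                qualifiers={"locus_tag": [g.locus_tag], "product": [g.product_text]},
            )
            rec.features.append(feat)
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def write_gff3(bundle: AnnotationBundle, gff_path: str | Path,
               fasta_path: Optional[str | Path] = None) -> None:
    lines = ["##gff-version 3"]
    for rep in bundle.replicons:
        lines.append(f"##sequence-region {rep.replicon_id} 1 {rep.length}")
    for rep in bundle.replicons:
        for g in rep.genes:
            attrs = f"ID={g.locus_tag};locus_tag={g.locus_tag}"
            if g.product_text:
                product = g.product_text.replace(";", "%3B").replace("=", "%3D")
                attrs += f";product={product}"
            lines.append(
                "\t".join(
                    [
                        rep.replicon_id,
                        "tfrctx",
                        "CDS",
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        "0",
                        attrs,
                    ]
                )
            )
    Path(gff_path).write_text("\n".join(lines) + "\n")
    if fasta_path is not None:
        write_fasta(
            {rep.replicon_id: rep.sequence for rep in bundle.replicons if rep.sequence},
            fasta_path,
        )


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            fh.write("\n".join(textwrap.wrap(seq, width)) + "\n")


def write_bed(intervals: Sequence[tuple[str, int, int, str]], path: str | Path) -> None:
    """Write (replicon, start1, end1, name) rows as 0-based half-open BED."""
    with open(path, "w") as fh:
        for rid, start1, end1, name in intervals:
            fh.write(f"{rid}\t{start1 - 1}\t{end1}\t{name}\n")
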