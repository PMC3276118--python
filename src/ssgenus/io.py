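"""Readers and writers for the standard interchange formats.

GFF3 carries gene models (with ``family``, ``status``, ``disruptions``
and ``cds_length`` attributes) and assembly gaps (feature type ``gap``);
FASTA carries genome and CDS sequences; plain TSV carries the
gene-to-family table, the ancestral gene order and per-gene rate records.

GFF3 lines are parsed with :func:`gffutils.feature.feature_from_line`
inside our own streaming loop so that malformed lines are reported with
their line number and duplicate gene IDs raise an integrity error.
Writing is plain text with a fixed attribute order, which makes
``write -> read -> write`` byte-stable on canonically sorted input.
"""

from __future__ import annotations

import os
from typing import Optional, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from gffutils.feature import feature_from_line

from .model import (
    AncestralOrder,
    GeneModel,
    GenomeAnnotation,
    IntegrityError,
    RateRecord,
    ScaffoldAnnotation,
)

PathLike = Union[str, os.PathLike]

GFF_VERSION_LINE = "##gff-version 3"
# serialization order for gene attributes; fixed for byte-stable output
_ATTR_ORDER = ("ID", "family", "status", "disruptions", "cds_length")


class GffParseError(ValueError):
    """A malformed GFF3 line, reported with its 1-based line number."""


def read_gff3(path: PathLike, species: Optional[str] = None) -> GenomeAnnotation:
    """Read one species' annotation from GFF3.

    Gene-like features (``gene``, ``pseudogene``) become
    :class:`~ssgenus.model.GeneModel`; ``gap`` features become assembly-gap
    intervals.  1-based inclusive GFF coordinates are converted to the
    internal 0-based half-open convention.  ``species`` defaults to the
    file's basename stem.
    """
    if species is None:
        species = os.path.splitext(os.path.basename(os.fspath(path)))[0]
    genome = GenomeAnnotation(species=species)
    seen_ids: set[str] = set()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GffParseError(f"{path}:{lineno}: malformed GFF3 line: {exc}") from exc
            if feat.featuretype == "gap":
                sc = genome.scaffolds.setdefault(
                    feat.seqid, ScaffoldAnnotation(feat.seqid)
                )
                sc.gaps.append((feat.start - 1, feat.end))
            elif feat.featuretype in ("gene", "pseudogene"):
                attrs = feat.attributes
                gid = attrs.get("ID", [None])[0]
                if gid is None:
                    raise GffParseError(f"{path}:{lineno}: gene feature without ID")
                if gid in seen_ids:
                    raise IntegrityError(f"{path}:{lineno}: duplicate gene ID {gid}")
                seen_ids.add(gid)
                family = attrs.get("family", [None])[0]
                status = attrs.get("status", ["intact"])[0]
                if feat.featuretype == "pseudogene" and status == "intact":
                    status = "pseudogene"
                gene = GeneModel(
                    id=gid,
                    species=species,
                    scaffold=feat.seqid,
                    start=feat.start - 1,
                    end=feat.end,
                    strand=feat.strand if feat.strand in ("+", "-") else "+",
                    status=status,
                    family=family,
                    n_disruptions=int(attrs.get("disruptions", ["0"])[0]),
                    cds_length=int(attrs.get("cds_length", ["0"])[0]),
                )
                genome.add_gene(gene)
            # other feature types are ignored
    genome.sort()
    genome.validate()
    return genome


def _format_gene(gene: GeneModel) -> str:
    ftype = "pseudogene" if gene.status == "pseudogene" else "gene"
    attrs = {
        "ID": gene.id,
        "family": gene.family,
        "status": gene.status,
        "disruptions": str(gene.n_disruptions),
        "cds_length": str(gene.cds_length),
    }
    attr_str = ";".join(f"{k}={attrs[k]}" for k in _ATTR_ORDER if attrs[k] is not None)
    return "\t".join(
        [
            gene.scaffold,
            "ssgenus",
            ftype,
            str(gene.start + 1),
            str(gene.end),
            ".",
            gene.strand,
            ".",
            attr_str,
        ]
    )


def write_gff3(genome: GenomeAnnotation, path: PathLike) -> None:
    """Write an annotation as GFF3 with deterministic ordering.

    Scaffolds are written in lexicographic order, features by start
    coordinate; gene attributes appear in fixed key order.
    """
    with open(path, "w") as fh:
        fh.write(GFF_VERSION_LINE + "\n")
        for sid in sorted(genome.scaffolds):
            sc = genome.scaffolds[sid]
            rows: list[tuple[int, str]] = []
            for g in sc.genes:
                rows.append((g.start, _format_gene(g)))
            for a, b in sc.gaps:
                rows.append(
                    (a, "\t".join([sid, "ssgenus", "gap", str(a + 1), str(b), ".", ".", ".", "."]))
                )
            for _, line in sorted(rows, key=lambda r: (r[0], r[1])):
                fh.write(line + "\n")


def read_family_table(path: PathLike) -> dict[str, str]:
    """Read the gene→ancestral-family TSV (columns ``gene_id``, ``family_id``).

    The table stands in for profile-HMM best matches: genes absent from it
    simply have no family.  Returns an empty map for an empty file.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError:
        return {}
    if df.empty:
        return {}
    if not {"gene_id", "family_id"}.issubset(df.columns):
        # headerless two-column fallback
        df = pd.read_csv(path, sep="\t", dtype=str, header=None, names=["gene_id", "family_id"])
    return dict(zip(df["gene_id"], df["family_id"]))


def write_family_table(families: dict[str, str], path: PathLike) -> None:
    pd.DataFrame(
        sorted(families.items()), columns=["gene_id", "family_id"]
    ).to_csv(path, sep="\t", index=False)


def read_ancestral_order(path: PathLike) -> AncestralOrder:
    """Read the ancestral-order TSV (columns ``family_id``, ``track``, ``chromosome``)."""
    df = pd.read_csv(path, sep="\t", dtype={"family_id": str, "track": str})
    chrom = (
        dict(zip(df["family_id"], df["chromosome"].astype(int)))
        if "chromosome" in df.columns
        else {}
    )
    return AncestralOrder(
        families=list(df["family_id"]),
        track=dict(zip(df["family_id"], df["track"])),
        chromosome=chrom,
    )


def write_ancestral_order(order: AncestralOrder, path: PathLike) -> None:
    pd.DataFrame(
        {
            "family_id": order.families,
            "track": [order.track[f] for f in order.families],
            "chromosome": [order.chromosome.get(f, 0) for f in order.families],
        }
    ).to_csv(path, sep="\t", index=False)


def read_rate_table(path: PathLike) -> list[RateRecord]:
    """Read per-gene rates from TSV (columns ``gene_id``, ``dN``, ``dS``)."""
    df = pd.read_csv(path, sep="\t")
    return [RateRecord(id=str(r.gene_id), dN=float(r.dN), dS=float(r.dS)) for r in df.itertuples()]


def read_fasta(path: PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(os.fspath(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, os.fspath(path), "fasta")
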