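"""Readers and writers for the pipeline's on-disk formats.

Everything is plain text: gene-catalog TSV, GFF3 (gene features with
synthetic 1-based coordinates), FASTA via Biopython, homolog-pair TSV,
an MCScanX-like collinear-block text layout, Ks TSV, mixture JSON, and
LTR-pair FASTA with ``::5p``/``::3p`` record suffixes.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .homology import HomologPair
from .ksdist import KsEstimate, MixtureModel
from .simulate import Genome, SimulatedLTRPair
from .synteny import Anchor, CollinearBlock

GENE_SPACING_BP = 2000  # synthetic genomic spacing between gene starts


# -- catalogs ---------------------------------------------------------------

def write_catalog(genome: Genome, path: str | Path) -> None:
    df = genome.catalog.copy()
    df.insert(0, "genome", genome.lineage)
    df.to_csv(path, sep="\t", index=False)


def read_catalog(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    need = {"gene_id", "chromosome", "rank"}
    if not need <= set(df.columns):
        raise ValueError(f"catalog {path} missing columns {need - set(df.columns)}")
    return df


def write_gff3(genome: Genome, path: str | Path) -> None:
    """Gene features only, synthetic 1-based coordinates from gene ranks."""
    cds_len = {g: len(s) for g, s in genome.cds.items()}
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genome.catalog.itertuples():
            start = row.rank * GENE_SPACING_BP + 1
            end = start + cds_len[row.gene_id] - 1
            fh.write(
                f"{row.chromosome}\twgdkit\tgene\t{start}\t{end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


# -- FASTA ------------------------------------------------------------------

def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=g, description="") for g, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), "fasta")}


# -- homolog pairs ----------------------------------------------------------

def write_pairs(pairs: list[HomologPair], path: str | Path) -> None:
    pd.DataFrame(
        [(p.gene_a, p.gene_b, p.score, p.identity, p.coverage) for p in pairs],
        columns=["gene_a", "gene_b", "score", "identity", "coverage"],
    ).to_csv(path, sep="\t", index=False)


def read_pairs(path: str | Path) -> list[HomologPair]:
    df = pd.read_csv(path, sep="\t")
    return [
        HomologPair(r.gene_a, r.gene_b, float(r.score), float(r.identity),
                    float(r.coverage))
        for r in df.itertuples()
    ]


# -- collinear blocks -------------------------------------------------------

def write_blocks(blocks: list[CollinearBlock], path: str | Path) -> None:
    """MCScanX-like text layout: one header line per block, then anchors."""
    with open(path, "w") as fh:
        for blk in blocks:
            ks = "" if blk.median_ks is None else f"\tmedian_ks={blk.median_ks:.4f}"
            fh.write(
                f"## block {blk.block_id}\t{blk.chrom_a}\t{blk.chrom_b}\t"
                f"{blk.orientation}\tscore={blk.score:.2f}\t"
                f"n={blk.n_anchors}{ks}\n"
            )
            for a in blk.anchors:
                fh.write(f"{a.gene_a}\t{a.gene_b}\t{a.rank_a}\t{a.rank_b}\n")


def read_blocks(path: str | Path) -> list[CollinearBlock]:
    blocks: list[CollinearBlock] = []
    current = None
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("## block"):
                parts = line.split("\t")
                bid = int(parts[0].split()[-1])
                chrom_a, chrom_b, orientation = parts[1], parts[2], parts[3]
                score = float(parts[4].split("=", 1)[1])
                median_ks = None
                for p in parts[5:]:
                    if p.startswith("median_ks="):
                        median_ks = float(p.split("=", 1)[1])
                current = CollinearBlock(bid, chrom_a, chrom_b, orientation,
                                         score, [], median_ks)
                blocks.append(current)
            else:
                ga, gb, ra, rb = line.split("\t")
                current.anchors.append(
                    Anchor(ga, gb, current.chrom_a, current.chrom_b,
                           int(ra), int(rb)))
    return blocks


# -- Ks tables and mixtures -------------------------------------------------

def write_ks_table(estimates: dict[tuple[str, str], KsEstimate],
                   path: str | Path) -> None:
    rows = []
    for (ga, gb), e in sorted(estimates.items()):
        rows.append((ga, gb, e.n_codons, e.S, e.N, e.Sd, e.Nd,
                     e.ka if e.ka is not None else "",
                     e.ks if e.ks is not None else "", e.valid))
    pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "n_codons", "S", "N", "Sd", "Nd",
                       "Ka", "Ks", "valid"],
    ).to_csv(path, sep="\t", index=False)


def write_mixture(model: MixtureModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump({
            "n_components": model.n_components,
            "components": [dataclasses.asdict(c) for c in model.components],
            "bic": model.bic,
            "bic_by_k": model.bic_by_k,
            "fit_range": list(model.fit_range),
            "n_values": model.n_values,
            "seed": model.seed,
        }, fh, indent=2)


# -- LTR pairs --------------------------------------------------------------

def write_ltr_fasta(pairs: list[SimulatedLTRPair], path: str | Path) -> None:
    records = []
    for p in pairs:
        records.append(SeqRecord(Seq(p.ltr5), id=f"{p.element_id}::5p",
                                 description=""))
        records.append(SeqRecord(Seq(p.ltr3), id=f"{p.element_id}::3p",
                                 description=""))
    SeqIO.write(records, str(path), "fasta")


def read_ltr_fasta(path: str | Path) -> list[SimulatedLTRPair]:
    """Read LTR pairs; elements lacking either LTR are skipped (only
    complete 5'/3' pairs are admitted)."""
    by_element: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "::" not in rec.id:
            raise ValueError(f"LTR record {rec.id!r} lacks ::5p/::3p suffix")
        elem, end = rec.id.rsplit("::", 1)
        by_element.setdefault(elem, {})[end] = str(rec.seq).upper()
    out = []
    for elem in sorted(by_element):
        d = by_element[elem]
        if "5p" in d and "3p" in d:
            out.append(SimulatedLTRPair(elem, d["5p"], d["3p"], None))
    return out
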