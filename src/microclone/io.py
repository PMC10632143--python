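"""Readers and writers for the formats the pipeline touches.

Mutation calls come in as VCF 4.x (via pysam) or a plain TSV; count
matrices as TSV with ``ALT_<sample>`` / ``DEP_<sample>`` columns; gene
annotation as BED6 plus an expression TSV; clone trees go out as Newick.
"""

from __future__ import annotations

import logging
import warnings
from typing import Optional

import dendropy
import numpy as np
import pandas as pd

from .core import (
    AnnotationTrack,
    CountMatrix,
    MutationCall,
    infer_mut_class,
)

log = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Mutation tables
# --------------------------------------------------------------------------


def read_mutation_table(path, format: str = "tsv", contigs=None) -> list[MutationCall]:
    """Read candidate mutation calls from a VCF or TSV file.

    Coordinates are preserved 1-based.  SBS/DBS/indel classes are inferred
    from ref/alt lengths.  A ``trinucleotide`` column (96-class label) is
    used when present in a TSV; otherwise contexts are left absent.
    Records on contigs not in ``contigs`` (when given) are skipped with a
    warning; malformed records raise with the offending line number.
    """
    if format == "vcf":
        return _read_vcf(path, contigs)
    if format == "tsv":
        return _read_tsv_calls(path, contigs)
    raise ValueError(f"unknown format {format!r}")


def _read_vcf(path, contigs) -> list[MutationCall]:
    import pysam

    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if contigs is not None and rec.chrom not in contigs:
                warnings.warn(f"skipping record on unknown contig {rec.chrom}")
                continue
            for alt in rec.alts or ():
                calls.append(
                    MutationCall(
                        chrom=rec.chrom,
                        pos=rec.pos,  # pysam exposes 1-based .pos
                        ref=rec.ref,
                        alt=alt,
                        mut_class=infer_mut_class(rec.ref, alt),
                    )
                )
    return calls


def _read_tsv_calls(path, contigs) -> list[MutationCall]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "pos", "ref", "alt"}
    if not required.issubset(df.columns):
        raise ValueError(f"mutation TSV needs columns {sorted(required)}")
    calls = []
    for lineno, row in enumerate(df.itertuples(index=False), start=2):
        try:
            if contigs is not None and row.chrom not in contigs:
                warnings.warn(f"skipping record on unknown contig {row.chrom}")
                continue
            calls.append(
                MutationCall(
                    chrom=row.chrom,
                    pos=int(row.pos),
                    ref=row.ref,
                    alt=row.alt,
                    mut_class=infer_mut_class(row.ref, row.alt),
                    trinucleotide=getattr(row, "trinucleotide", None) or None,
                    gene_id=getattr(row, "gene_id", None) or None,
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"malformed record at line {lineno}: {exc}") from exc
    return calls


# --------------------------------------------------------------------------
# Count matrices
# --------------------------------------------------------------------------


def read_count_matrix(path) -> CountMatrix:
    """Read a mutations × samples count matrix from TSV.

    Missing cells are treated as depth 0.  A cell with alt > depth or a
    duplicated mutation key is an error naming the offender.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return count_matrix_from_frame(df)


def count_matrix_from_frame(df: pd.DataFrame) -> CountMatrix:
    alt_cols = [c for c in df.columns if c.startswith("ALT_")]
    samples = [c[4:] for c in alt_cols]
    keys = (
        df["chrom"].astype(str)
        + ":" + df["pos"].astype(str)
        + ":" + df["ref"] + ">" + df["alt"]
    )
    dup = keys[keys.duplicated()]
    if len(dup):
        raise ValueError(f"duplicated mutation key {dup.iloc[0]}")
    mutations = [
        MutationCall(
            chrom=str(r.chrom), pos=int(r.pos), ref=r.ref, alt=r.alt,
            mut_class=infer_mut_class(r.ref, r.alt),
            trinucleotide=getattr(r, "trinucleotide", None) or None,
            gene_id=getattr(r, "gene_id", None) or None,
        )
        for r in df.itertuples(index=False)
    ]
    alt = df[alt_cols].fillna(0).to_numpy(dtype=np.int64)
    dep = df[[f"DEP_{s}" for s in samples]].fillna(0).to_numpy(dtype=np.int64)
    return CountMatrix(mutations, samples, alt, dep)


def write_count_matrix(matrix: CountMatrix, path) -> None:
    matrix.to_frame().to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------------------
# Gene annotation
# --------------------------------------------------------------------------


def read_gene_annotation(bed_path, expression_path=None) -> AnnotationTrack:
    """Read genes from BED6 (+ optional two-column gene/expression TSV).

    BED is 0-based half-open on disk; positions are converted to the
    package's 1-based convention (start+1) with half-open [start, end).
    The TSS is the 5' end of the interval given the strand.
    """
    bed = pd.read_csv(
        bed_path, sep="\t", header=None,
        names=["chrom", "start0", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str},
    )
    genes = pd.DataFrame(
        {
            "chrom": bed["chrom"],
            "strand": bed["strand"],
            "start": bed["start0"] + 1,
            "end": bed["end"] + 1,
            "expression": np.nan,
        },
        index=pd.Index(bed["gene_id"], name="gene_id"),
    )
    genes["tss"] = np.where(genes["strand"] == "+", genes["start"], genes["end"] - 1)
    if expression_path is not None:
        expr = pd.read_csv(expression_path, sep="\t", index_col=0)
        genes["expression"] = expr.iloc[:, 0].reindex(genes.index)
    return AnnotationTrack(genes=genes)


# --------------------------------------------------------------------------
# Newick clone trees
# --------------------------------------------------------------------------


def write_newick(tree, path) -> None:
    """Write a clone forest as Newick rooted at the (unlabelled) germline.

    Branch lengths are branch mutation counts; node labels are cluster ids.
    """
    path = str(path)
    with open(path, "w") as fh:
        fh.write(newick_string(tree) + "\n")


def newick_string(tree) -> str:
    def render(node_id: str) -> str:
        kids = tree.children(node_id)
        node = tree.nodes[node_id]
        inner = ""
        if kids:
            inner = "(" + ",".join(render(k) for k in sorted(kids)) + ")"
        return f"{inner}{node_id}:{node.branch_length:g}"

    roots = sorted(tree.roots())
    return "(" + ",".join(render(r) for r in roots) + ");"


def read_newick(path):
    """Read a clone forest written by :func:`write_newick`."""
    from .phylogeny import CloneNode, CloneTree

    dtree = dendropy.Tree.get(
        path=str(path), schema="newick", suppress_internal_node_taxa=False
    )
    nodes = {}

    def walk(dnode, parent_id):
        for child in dnode.child_nodes():
            label = child.taxon.label if child.taxon else child.label
            label = label.replace(" ", "_") if label else label
            nodes[label] = CloneNode(
                cluster_id=label,
                parent=parent_id,
                branch_length=float(child.edge.length or 0.0),
            )
            walk(child, label)

    walk(dtree.seed_node, None)
    return CloneTree(nodes=nodes)
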