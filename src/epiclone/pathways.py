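"""Pathway-normalization calls from clone-level demethylation.

Four colon-cancer pathways are scored: complete demethylation of any one
member gene's promoter block in a clone re-activates that gene and is
taken to normalize the pathway in that clone. Most genes are evaluated at
their TSS200 CpG-island block; genes lacking one (CDKN2A on the 450K
array) fall back to the block most 5′ of exon 1, resolved strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .blocks import BETA_UNMETH, BlockDefinition
from .simulate import InputError

#: default member genes per pathway; override via a plain-text gene-set file
# (MIR34B is listed under its own symbol; if an annotation carries its CGI
#  under a host gene, supply a custom gene-set file with that symbol)
DEFAULT_GENE_SETS: dict[str, tuple[str, ...]] = {
    "cell_cycle": ("CDKN2A", "CHFR"),
    "WNT": ("DKK3", "SFRP1", "SFRP2", "SFRP5", "SOX17", "WIF1"),
    "p53": ("IGFBP7", "MIR34B"),
    "TGF-beta": ("BMP2", "BMP3", "BMP6", "BMPR1B"),
}


class GeneLookupError(KeyError):
    """A pathway gene could not be resolved to a genomic block."""


@dataclass
class GeneInfo:
    """Coordinates needed for the exon-1 fallback of CGI-less genes."""

    exon1_start: int
    strand: str  # "+" | "-"


@dataclass
class PathwayCallTable:
    """Boolean normalization calls, clones × pathways, with evidence."""

    calls: pd.DataFrame
    evidence: dict[tuple[str, str], list[tuple[str, str, float]]] = field(default_factory=dict)
    # (clone, pathway) -> [(gene, block_id, beta), ...]

    def to_json_dict(self) -> dict:
        return {
            "calls": {
                clone: {p: bool(v) for p, v in row.items()}
                for clone, row in self.calls.iterrows()
            },
            "evidence": {
                f"{clone}|{pathway}": [
                    {"gene": g, "block_id": b, "beta": beta} for g, b, beta in ev
                ]
                for (clone, pathway), ev in self.evidence.items()
            },
        }


def load_gene_sets(path: str | Path) -> dict[str, tuple[str, ...]]:
    """Read a two-column TSV (pathway, gene) into a gene-set mapping."""
    frame = pd.read_csv(path, sep="\t", comment="#", names=["pathway", "gene"], header=None)
    out: dict[str, list[str]] = {}
    for row in frame.itertuples(index=False):
        out.setdefault(str(row.pathway), [])
        if row.gene in out[str(row.pathway)]:
            raise InputError(f"duplicate gene {row.gene} in pathway {row.pathway}")
        out[str(row.pathway)].append(str(row.gene))
    return {k: tuple(v) for k, v in out.items()}


def write_gene_sets(gene_sets: dict[str, tuple[str, ...]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for pathway, genes in gene_sets.items():
            for gene in genes:
                fh.write(f"{pathway}\t{gene}\n")


def resolve_gene_block(
    gene: str,
    blocks: list[BlockDefinition],
    gene_info: dict[str, GeneInfo] | None = None,
) -> str:
    """Resolve a gene to the block its methylation is evaluated at.

    Preference: the gene's TSS200 CpG-island block. If the gene has none
    (CDKN2A-like) and coordinates are supplied, the candidate block most 5′
    of exon 1 is chosen — lowest start on the + strand, highest end on the
    − strand.
    """
    candidates = [b for b in blocks if b.gene == gene]
    if not candidates:
        known = sorted({b.gene for b in blocks if b.gene})
        raise GeneLookupError(
            f"gene {gene!r} not found in block annotations; known genes include "
            f"{known[:10]}"
        )
    tss200cgi = [b for b in candidates if b.region_class == "TSS200" and b.cgi_class == "island"]
    if tss200cgi:
        return tss200cgi[0].block_id
    if gene_info is None or gene not in gene_info:
        raise GeneLookupError(
            f"gene {gene!r} has no TSS200 CGI block and no exon-1 coordinates; "
            f"candidates: {[b.block_id for b in candidates]}"
        )
    info = gene_info[gene]
    if info.strand == "+":
        best = min(candidates, key=lambda b: (b.start, b.block_id))
    elif info.strand == "-":
        best = max(candidates, key=lambda b: (b.end, b.block_id))
    else:
        raise InputError(f"invalid strand {info.strand!r} for gene {gene!r}")
    return best.block_id


def evaluate_pathways(
    block_betas: pd.DataFrame,
    blocks: list[BlockDefinition],
    clone_ids: list[str],
    gene_sets: dict[str, tuple[str, ...]] | None = None,
    gene_info: dict[str, GeneInfo] | None = None,
    beta_unmeth: float = BETA_UNMETH,
    skip_missing: bool = False,
) -> PathwayCallTable:
    """Call pathway normalization per clone.

    A pathway is normalized in a clone iff ≥ 1 member gene's resolved block
    has β < 0.2 there; every true call records its supporting genes.
    Unresolvable genes raise unless ``skip_missing``, in which case they
    are dropped with a flag in the evidence under ``("*", pathway)``.
    """
    gene_sets = gene_sets or DEFAULT_GENE_SETS
    resolved: dict[str, str] = {}
    skipped: dict[str, list[str]] = {}
    for pathway, genes in gene_sets.items():
        for gene in genes:
            try:
                resolved[gene] = resolve_gene_block(gene, blocks, gene_info)
            except GeneLookupError:
                if not skip_missing:
                    raise
                skipped.setdefault(pathway, []).append(gene)

    calls = pd.DataFrame(False, index=clone_ids, columns=list(gene_sets))
    evidence: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    for pathway, genes in gene_sets.items():
        for clone in clone_ids:
            support = []
            for gene in genes:
                if gene not in resolved:
                    continue
                block_id = resolved[gene]
                if block_id not in block_betas.index:
                    raise InputError(f"block {block_id} (gene {gene}) has no β data")
                beta = block_betas.loc[block_id, clone]
                if pd.notna(beta) and beta < beta_unmeth:
                    support.append((gene, block_id, float(beta)))
            if support:
                calls.loc[clone, pathway] = True
                evidence[(clone, pathway)] = support
    for pathway, genes in skipped.items():
        evidence[("*", pathway)] = [(g, "UNRESOLVED", float("nan")) for g in genes]
    return PathwayCallTable(calls=calls, evidence=evidence)


def write_pathway_calls_tsv(table: PathwayCallTable, path: str | Path) -> None:
    table.calls.astype(int).to_csv(path, sep="\t", index_label="clone")
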