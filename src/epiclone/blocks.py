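"""Probe-to-block assembly, block β aggregation, and methylation states.

Infinium array probes annotated by gene, TSS-relative region class and CGI
relation are grouped into genomic blocks; a block's methylation level is
the mean β of its member probes, and each level is classified as
unmethylated (β < 0.2), partially methylated (0.2 ≤ β < 0.8) or fully
methylated (β ≥ 0.8).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import InputError

REGION_CLASSES = ("TSS200", "TSS1500", "body", "intergenic")
CGI_CLASSES = ("island", "shore", "shelf", "open_sea")

#: maximum gap (bp) between consecutive intergenic probes in one block
INTERGENIC_GAP_BP = 1000

BETA_UNMETH = 0.2
BETA_FULL = 0.8


class MethState(str, Enum):
    UNMETHYLATED = "unmethylated"
    PARTIALLY_METHYLATED = "partially_methylated"
    FULLY_METHYLATED = "fully_methylated"
    MISSING = "missing"


@dataclass(frozen=True)
class ProbeRecord:
    probe_id: str
    chrom: str
    pos: int  # 1-based
    gene: str
    region_class: str
    cgi_class: str


@dataclass(frozen=True)
class BlockDefinition:
    """A group of probes sharing gene, region class and CGI class.

    block_id is deterministic from those three keys (intergenic blocks key
    on chromosome, CGI class and a contiguity run instead of a gene).
    """

    block_id: str
    probe_ids: tuple[str, ...]
    gene: str
    region_class: str
    cgi_class: str
    chrom: str
    start: int
    end: int


def _manifest_to_records(manifest) -> pd.DataFrame:
    if isinstance(manifest, pd.DataFrame):
        frame = manifest.copy()
    else:
        frame = pd.DataFrame([r.__dict__ for r in manifest])
    required = {"probe_id", "chrom", "pos", "gene", "region_class", "cgi_class"}
    missing = required - set(frame.columns)
    if missing:
        raise InputError(f"manifest lacks columns: {sorted(missing)}")
    return frame


def assemble_blocks(manifest) -> list[BlockDefinition]:
    """Group probes into genomic blocks.

    Genic probes group by (gene, region_class, cgi_class). Intergenic
    probes group by (chrom, cgi_class) and are split wherever consecutive
    probes are more than ``INTERGENIC_GAP_BP`` apart. Every probe lands in
    exactly one block; output is sorted by block_id.
    """
    frame = _manifest_to_records(manifest)
    if frame.empty:
        raise InputError("manifest is empty")
    if frame["probe_id"].duplicated().any():
        dups = frame.loc[frame["probe_id"].duplicated(), "probe_id"].tolist()
        raise InputError(f"duplicate probe_id(s): {dups[:5]}")

    blocks: list[BlockDefinition] = []

    genic = frame[frame["region_class"] != "intergenic"]
    for (gene, region, cgi), grp in genic.groupby(
        ["gene", "region_class", "cgi_class"], sort=True
    ):
        grp = grp.sort_values(["chrom", "pos", "probe_id"])
        blocks.append(
            BlockDefinition(
                block_id=f"{gene}|{region}|{cgi}",
                probe_ids=tuple(grp["probe_id"]),
                gene=str(gene),
                region_class=str(region),
                cgi_class=str(cgi),
                chrom=str(grp["chrom"].iloc[0]),
                start=int(grp["pos"].min()),
                end=int(grp["pos"].max()),
            )
        )

    intergenic = frame[frame["region_class"] == "intergenic"]
    for (chrom, cgi), grp in intergenic.groupby(["chrom", "cgi_class"], sort=True):
        grp = grp.sort_values(["pos", "probe_id"])
        run_break = grp["pos"].diff().fillna(0) > INTERGENIC_GAP_BP
        for _, run in grp.groupby(run_break.cumsum()):
            start, end = int(run["pos"].min()), int(run["pos"].max())
            blocks.append(
                BlockDefinition(
                    block_id=f"{chrom}:{start}-{end}|intergenic|{cgi}",
                    probe_ids=tuple(run["probe_id"]),
                    gene="",
                    region_class="intergenic",
                    cgi_class=str(cgi),
                    chrom=str(chrom),
                    start=start,
                    end=end,
                )
            )

    return sorted(blocks, key=lambda b: b.block_id)


def aggregate_block_beta(
    probe_table: pd.DataFrame, blocks: list[BlockDefinition]
) -> pd.DataFrame:
    """Block β matrix (blocks × samples): mean of non-missing member probes.

    A block's value is missing only when every member probe is missing for
    that sample.
    """
    unknown = [p for b in blocks for p in b.probe_ids if p not in probe_table.index]
    if unknown:
        raise InputError(f"blocks reference unknown probe_id(s): {unknown[:5]}")
    membership = pd.Series(
        {p: b.block_id for b in blocks for p in b.probe_ids}, name="block_id"
    )
    covered = probe_table.loc[membership.index]
    out = covered.groupby(membership).mean()  # skips NaN; all-NaN → NaN
    return out.reindex([b.block_id for b in blocks])


def classify_state(beta) -> MethState | np.ndarray:
    """Classify β into the three methylation states (vectorised over arrays).

    Boundaries are half-open: 0.2 is partial, 0.8 is full. NaN maps to the
    missing sentinel; values outside [0, 1] raise.
    """
    arr = np.asarray(beta, dtype=float)
    if np.any((arr < 0) | (arr > 1)):
        raise InputError("β values must lie in [0, 1]")
    states = np.empty(arr.shape, dtype=object)
    states[...] = MethState.MISSING
    states[arr < BETA_UNMETH] = MethState.UNMETHYLATED
    states[(arr >= BETA_UNMETH) & (arr < BETA_FULL)] = MethState.PARTIALLY_METHYLATED
    states[arr >= BETA_FULL] = MethState.FULLY_METHYLATED
    if np.ndim(beta) == 0:
        return states.item()
    return states


def select_fully_methylated_tss200cgi(
    block_betas: pd.DataFrame,
    blocks: list[BlockDefinition],
    baseline_sample: str,
    beta_full: float = BETA_FULL,
) -> list[str]:
    """Block ids of TSS200-island blocks fully methylated at baseline.

    These are the candidate promoters whose complete demethylation is
    scored in treated clones.
    """
    if baseline_sample not in block_betas.columns:
        raise InputError(f"unknown baseline sample {baseline_sample!r}")
    tss200cgi = [
        b.block_id
        for b in blocks
        if b.region_class == "TSS200" and b.cgi_class == "island"
    ]
    baseline = block_betas.loc[tss200cgi, baseline_sample]
    return [bid for bid in tss200cgi if baseline[bid] >= beta_full]


def block_totals(block_betas: pd.DataFrame) -> dict[str, int]:
    """Report both block universes: all blocks, and complete-case blocks.

    Genome-wide analyses sometimes quote the number of assembled blocks and
    sometimes only those with data in every sample; both are returned.
    """
    return {
        "all_blocks": int(block_betas.shape[0]),
        "blocks_nonmissing_in_all_samples": int(block_betas.dropna().shape[0]),
    }


# ---------------------------------------------------------------------------
# plain-text I/O (TSV; missing token "NA")

def read_manifest_tsv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, sep="\t", dtype={"probe_id": str, "chrom": str, "gene": str})
    frame["gene"] = frame["gene"].fillna("")  # intergenic probes carry no gene
    return frame


def read_probe_table_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="probe_id", na_values=["NA"])


def write_probe_table_tsv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index_label="probe_id", na_rep="NA")


def write_manifest_tsv(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def write_block_definitions_tsv(blocks: list[BlockDefinition], path: str | Path) -> None:
    """BED-like TSV: chrom, start, end, block_id, gene, region_class, cgi_class."""
    frame = pd.DataFrame(
        [
            (b.chrom, b.start, b.end, b.block_id, b.gene, b.region_class, b.cgi_class)
            for b in blocks
        ],
        columns=["chrom", "start", "end", "block_id", "gene", "region_class", "cgi_class"],
    )
    frame.to_csv(path, sep="\t", index=False)


def read_block_definitions_tsv(path: str | Path, manifest: pd.DataFrame) -> list[BlockDefinition]:
    """Load a precomputed block file, recovering membership from the manifest.

    Genic blocks recover members by (gene, region_class, cgi_class);
    intergenic blocks by coordinate span. This lets externally assembled
    blocks (e.g. from published processing) override the built-in rules.
    """
    frame = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str})
    frame["gene"] = frame["gene"].fillna("")
    manifest = _manifest_to_records(manifest)
    out = []
    for row in frame.itertuples(index=False):
        if row.region_class != "intergenic":
            members = manifest[
                (manifest["gene"] == row.gene)
                & (manifest["region_class"] == row.region_class)
                & (manifest["cgi_class"] == row.cgi_class)
            ]
        else:
            members = manifest[
                (manifest["chrom"] == row.chrom)
                & (manifest["cgi_class"] == row.cgi_class)
                & (manifest["pos"] >= row.start)
                & (manifest["pos"] <= row.end)
                & (manifest["region_class"] == "intergenic")
            ]
        if members.empty:
            raise InputError(f"block {row.block_id} matches no manifest probes")
        members = members.sort_values(["chrom", "pos", "probe_id"])
        out.append(
            BlockDefinition(
                block_id=row.block_id,
                probe_ids=tuple(members["probe_id"]),
                gene=row.gene,
                region_class=row.region_class,
                cgi_class=row.cgi_class,
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
            )
        )
    return out


def write_block_beta_tsv(block_betas: pd.DataFrame, path: str | Path) -> None:
    block_betas.to_csv(path, sep="\t", index_label="block_id", na_rep="NA")


def read_block_beta_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="block_id", na_values=["NA"])
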