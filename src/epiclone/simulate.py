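"""Synthetic single-cell demethylation data.

Generates the truth layer (per-cell demethylated-allele fractions in
{0, 0.5, 1}), derives bulk and clone β profiles from it, expands loci into
noisy array-style probe tables, and draws methylation-coupled UMI count
matrices. A single global seed drives fixed, named substreams so every
stage is reproducible on its own.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import SimParams, ParameterError

# fixed substream ids: changing one stage's draws never shifts another's
_STAGES = {
    "population": 0,
    "mock_population": 1,
    "dead_population": 2,
    "founders": 3,
    "probe_noise": 4,
    "umi": 5,
}

#: probe β values at the boundary are nudged into the open interval so the
#: Beta noise distribution is well defined on proportions
BETA_FLOOR = 1e-3


def _rng(params: SimParams, stage: str, extra: int = 0) -> np.random.Generator:
    ss = np.random.SeedSequence(entropy=params.seed, spawn_key=(_STAGES[stage], extra))
    return np.random.default_rng(ss)


class InputError(ValueError):
    """Raised when an operation receives structurally invalid input."""


@dataclass
class CellMethylome:
    """Per-cell, per-locus demethylated-allele fractions.

    ``fractions`` is cells × loci with entries in {0, 0.5, 1}: the share of
    a cell's two alleles that are demethylated. Baseline-unmethylated
    background loci are 1 for every cell.
    """

    fractions: pd.DataFrame
    silenced_loci: list[str]
    background_loci: list[str]

    @property
    def cell_ids(self) -> list[str]:
        return list(self.fractions.index)

    @property
    def locus_ids(self) -> list[str]:
        return list(self.fractions.columns)


@dataclass
class SampleBetaProfile:
    """Noise-free per-locus β values for one sample.

    β = 1 − demethylated-allele fraction averaged over the sample's cells;
    a clone averages over exactly one founder cell.
    """

    betas: pd.Series
    label: str
    kind: str  # bulk-mock | bulk-treated | clone | dead-pool
    founder: str | None = None


# silenced loci lead with known methylation-silenced genes of the modelled
# cell line: the four pathway gene sets, further TSGs, and two ERVs; the
# remainder are generic. CDKN2A is annotated without a TSS200 CGI block
# (its promoter lacks island probes) to exercise the exon-1 fallback.
NAMED_SILENCED_LOCI = (
    "CDKN2A", "CHFR",
    "DKK3", "SFRP1", "SFRP2", "SFRP5", "SOX17", "WIF1",
    "IGFBP7", "MIR34B",
    "BMP2", "BMP3", "BMP6", "BMPR1B",
    "FBLN2", "ICAM4",
    "ERVMER61-1", "ERVW-1",
)


def _locus_names(params: SimParams) -> tuple[list[str], list[str]]:
    named = list(NAMED_SILENCED_LOCI[: params.n_loci])
    width = max(4, len(str(params.n_loci)))
    generic = [f"TSG{i:0{width}d}" for i in range(1, params.n_loci - len(named) + 1)]
    width_bg = max(4, len(str(params.n_background_loci)))
    background = [f"BG{i:0{width_bg}d}" for i in range(1, params.n_background_loci + 1)]
    return named + generic, background


def simulate_population(
    params: SimParams, kind: str = "treated"
) -> CellMethylome:
    """Draw a cell population under the two-allele demethylation model.

    For each cell and silenced locus, each of the 2 initially methylated
    alleles independently demethylates with probability ``p_demeth``
    (``kind='treated'``), ``p_demeth × dead_multiplier`` (``'dead'``) or 0
    (``'mock'``); the entry is (# demethylated alleles)/2. Background loci
    are 1 (unmethylated) for every cell.
    """
    if kind == "treated":
        p, stage = params.p_demeth, "population"
    elif kind == "mock":
        p, stage = 0.0, "mock_population"
    elif kind == "dead":
        # extra demethylation in the dead pool, capped at certainty
        p, stage = min(1.0, params.p_demeth * params.dead_multiplier), "dead_population"
    else:
        raise InputError(f"unknown population kind {kind!r}")

    rng = _rng(params, stage)
    silenced, background = _locus_names(params)
    demeth = rng.binomial(2, p, size=(params.n_cells, params.n_loci)) / 2.0
    frame = pd.DataFrame(
        np.hstack([demeth, np.ones((params.n_cells, params.n_background_loci))]),
        index=[f"cell{i:05d}" for i in range(params.n_cells)],
        columns=silenced + background,
    )
    return CellMethylome(frame, silenced, background)


def derive_bulk(pop: CellMethylome, label: str = "bulk", kind: str = "bulk-treated") -> SampleBetaProfile:
    """Noise-free bulk β: per locus, 1 − mean demethylated-allele fraction."""
    if pop.fractions.empty:
        raise InputError("population is empty")
    betas = 1.0 - pop.fractions.mean(axis=0)
    return SampleBetaProfile(betas=betas, label=label, kind=kind)


def derive_clones(pop: CellMethylome, params: SimParams) -> list[SampleBetaProfile]:
    """Expand ``n_clones`` single founder cells into clone β profiles.

    Inheritance is faithful: clone β at a locus is 1 − the founder's
    demethylated-allele fraction. Founders are sampled without replacement.
    """
    if params.n_clones > len(pop.cell_ids):
        raise InputError(
            f"n_clones ({params.n_clones}) exceeds population size ({len(pop.cell_ids)})"
        )
    rng = _rng(params, "founders")
    founder_idx = rng.choice(len(pop.cell_ids), size=params.n_clones, replace=False)
    clones = []
    for k, idx in enumerate(founder_idx, start=1):
        founder = pop.cell_ids[idx]
        betas = 1.0 - pop.fractions.iloc[idx]
        clones.append(
            SampleBetaProfile(betas=betas, label=f"clone{k:02d}", kind="clone", founder=founder)
        )
    return clones


def emit_probe_table(
    profiles: list[SampleBetaProfile], params: SimParams
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expand loci into noisy probe-level β values plus a probe manifest.

    Each locus becomes ``probes_per_block`` probes; the observed probe β is
    Beta-distributed on [0, 1] with mean equal to the noise-free β (floored
    into the open interval) and the stated concentration. The manifest
    assigns each probe its locus's gene, region class TSS200, and CGI class
    island (silenced) or open_sea (background).

    Returns ``(probe_table, manifest)``: probe_table is probes × samples,
    manifest has columns probe_id, chrom, pos, gene, region_class, cgi_class.
    """
    if params.probes_per_block < 1:
        raise ParameterError("probes_per_block must be ≥ 1")
    if not profiles:
        raise InputError("no profiles given")

    loci = list(profiles[0].betas.index)
    silenced, background = _locus_names(params)
    silenced_set = set(silenced)
    if set(loci) != set(silenced) | set(background):
        # profiles from a foreign population: treat all as island loci
        silenced_set = set(loci)

    m = params.probes_per_block
    probe_ids, chroms, poss, genes, regions, cgis = [], [], [], [], [], []
    for i, locus in enumerate(loci):
        for j in range(m):
            probe_ids.append(f"{locus}_p{j + 1}")
            chroms.append("chr1")
            poss.append(i * 1_000_000 + j * 100 + 1)
            genes.append(locus)
            if locus == "CDKN2A":
                # promoter island not covered: evaluated at a TSS1500 shore
                # block via the most-5′-of-exon-1 rule downstream
                regions.append("TSS1500")
                cgis.append("shore")
            else:
                regions.append("TSS200")
                cgis.append("island" if locus in silenced_set else "open_sea")
    manifest = pd.DataFrame(
        {
            "probe_id": probe_ids,
            "chrom": chroms,
            "pos": poss,
            "gene": genes,
            "region_class": regions,
            "cgi_class": cgis,
        }
    )

    kappa = params.beta_noise_concentration
    rng = _rng(params, "probe_noise")
    data = {}
    for profile in profiles:
        truth = np.repeat(profile.betas.to_numpy(), m)
        mean = np.clip(truth, BETA_FLOOR, 1.0 - BETA_FLOOR)
        data[profile.label] = rng.beta(mean * kappa, (1.0 - mean) * kappa)
    table = pd.DataFrame(data, index=probe_ids)
    table.index.name = "probe_id"
    return table, manifest


VALID_ROLES = {"TSG", "ERV", "ISG", "background"}


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, size_r: float) -> np.ndarray:
    """Negative-binomial counts with the given per-cell means and size r."""
    counts = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if pos.any():
        p = size_r / (size_r + mean[pos])
        counts[pos] = rng.negative_binomial(size_r, p)
    return counts


def simulate_umi_matrix(
    pop: CellMethylome,
    params: SimParams,
    gene_roles: dict[str, str],
    condition: str = "treated",
):
    """Draw a genes × cells UMI count matrix coupled to the methylome.

    TSG/ERV genes must be loci of ``pop``: their per-cell mean is
    ``expr_mean × demethylated-allele fraction``. ISG genes carry no
    methylation entry; their mean is ``expr_mean × (1 + γ × #ERV loci with
    fraction ≥ 0.5 in the cell)``, an interferon response driven by ERV
    activation. Background genes have constant mean ``expr_mean``. Counts
    are overdispersed (negative binomial with size ``expr_dispersion``).
    """
    from .scrna import UMICountMatrix  # local import to avoid a cycle

    for gene, role in gene_roles.items():
        if role not in VALID_ROLES:
            raise InputError(f"unknown role {role!r} for gene {gene!r}")
        if role in ("TSG", "ERV") and gene not in pop.fractions.columns:
            raise InputError(f"{role} gene {gene!r} has no methylation entry")

    rng = _rng(params, "umi", extra=0 if condition == "mock" else 1)
    n_cells = len(pop.cell_ids)
    erv_genes = [g for g, r in gene_roles.items() if r == "ERV"]
    if erv_genes:
        erv_active = (pop.fractions[erv_genes].to_numpy() >= 0.5).sum(axis=1)
    else:
        erv_active = np.zeros(n_cells)

    genes = sorted(gene_roles)
    rows = np.zeros((len(genes), n_cells), dtype=np.int64)
    for gi, gene in enumerate(genes):
        role = gene_roles[gene]
        if role in ("TSG", "ERV"):
            mean = params.expr_mean * pop.fractions[gene].to_numpy()
        elif role == "ISG":
            mean = params.expr_mean * (1.0 + params.isg_coupling * erv_active)
        else:
            mean = np.full(n_cells, params.expr_mean)
        rows[gi] = _nb_counts(rng, mean, params.expr_dispersion)

    counts = pd.DataFrame(rows, index=genes, columns=pop.cell_ids)
    return UMICountMatrix(counts=counts, condition=pd.Series(condition, index=pop.cell_ids))
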