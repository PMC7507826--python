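"""Simulation parameters for the two-allele demethylation model.

A near-diploid cancer cell carries two methylated epialleles at each
silenced promoter CGI. Exposure to a demethylating drug gives each allele
an independent chance ``p_demeth`` of losing its methylation, so at the
single-cell level a locus ends up with a demethylated-allele fraction of
0, 0.5 or 1 — never anything in between. Everything downstream (bulk
averages, clone profiles, probe noise, methylation-coupled expression)
is driven by this truth layer.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace
from pathlib import Path

import yaml


class ParameterError(ValueError):
    """Raised when simulation parameters violate their invariants."""


@dataclass(frozen=True)
class SimParams:
    """Parameters of the synthetic demethylation study.

    Attributes
    ----------
    n_loci:
        Number of silenced loci. The first is a CGI-less promoter
        (CDKN2A-like, evaluated by the exon-1 fallback); the default 1040
        therefore yields 1039 baseline fully methylated TSS200 CGIs.
    n_background_loci:
        Number of baseline-unmethylated loci (open-sea background).
    n_cells:
        Cells in the treated (or mock) population.
    n_clones:
        Single-cell clones sampled from the treated population.
    p_demeth:
        Per-allele demethylation probability in [0, 1].
    probes_per_block:
        Array probes emitted per locus when writing a probe-level table.
    beta_noise_concentration:
        Concentration of the Beta noise around the noise-free block β;
        larger means tighter probes.
    expr_mean:
        Mean UMI count of a fully demethylated gene in one cell.
    expr_dispersion:
        Negative-binomial dispersion (size) of UMI counts.
    isg_coupling:
        γ: interferon-stimulated gene mean is scaled by (1 + γ × number of
        active ERV loci in the cell).
    dead_multiplier:
        Factor applied to ``p_demeth`` for the optional dead-cell pool.
    seed:
        Global seed; per-stage substreams are derived from it.
    """

    n_loci: int = 1040
    n_background_loci: int = 960
    n_cells: int = 1751
    n_clones: int = 9
    p_demeth: float = 0.3
    probes_per_block: int = 3
    beta_noise_concentration: float = 100.0
    expr_mean: float = 5.0
    expr_dispersion: float = 1.0
    isg_coupling: float = 1.0
    dead_multiplier: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_demeth <= 1.0:
            raise ParameterError(f"p_demeth must be in [0, 1], got {self.p_demeth}")
        if self.dead_multiplier < 0:
            raise ParameterError(
                f"dead_multiplier must be nonnegative, got {self.dead_multiplier}"
            )
        for name in ("n_loci", "n_background_loci", "n_cells", "n_clones", "probes_per_block"):
            value = getattr(self, name)
            if not isinstance(value, int) or value < 1:
                raise ParameterError(f"{name} must be a positive integer, got {value!r}")
        for name in ("beta_noise_concentration", "expr_mean", "expr_dispersion"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)!r}")
        if self.isg_coupling < 0:
            raise ParameterError(f"isg_coupling must be nonnegative, got {self.isg_coupling!r}")
        if self.n_clones > self.n_cells:
            raise ParameterError(
                f"n_clones ({self.n_clones}) cannot exceed n_cells ({self.n_cells})"
            )

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "SimParams":
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimParams":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def with_(self, **kwargs) -> "SimParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)
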