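"""Seeded generator of synthetic Ct tables with controlled statistical structure.

The generative model produces the quantities the stability methods consume:

``Ct_gs = baseline_g + shift_{g, group(s)} + b_s + sqrt(sd_g^2 - sd_b^2) * (l_g * u_s + sqrt(1 - l_g^2) * z_gs)``

where ``b_s ~ N(0, sd_b)`` is a per-sample effect shared across genes
(pipetting / RT-input variation — the positive inter-gene correlation the
BestKeeper index presumes), ``u_s`` is a standardized latent shared by
co-regulated genes and the target, and ``z_gs`` is independent noise.  The
bracketed term is scaled so that each gene's *total* marginal SD equals its
configured SD, keeping the descriptive statistics honest regardless of how
much of the variance is shared.

The loading ``l_g`` of a co-regulated gene is solved from the requested
Pearson coupling ``c`` against the target (which loads the latent fully),
so the gene–target correlation converges to ``c`` as the sample count grows:

``l_g = (c * sd_g * sd_T - sd_b^2) / (sqrt(sd_g^2 - sd_b^2) * sqrt(sd_T^2 - sd_b^2))``

Noise is Gaussian on the Ct scale: Ct is already a log-domain quantity, and
dispersion is conventionally reported in cycles.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .ctdata import CtTable

__all__ = [
    "SimulationConfig",
    "TruthRecord",
    "simulate_ct",
    "default_3t3l1_config",
]


@dataclass
class SimulationConfig:
    """Parameters of the synthetic Ct generator.

    Attributes
    ----------
    baseline_ct
        Per-gene mean Ct (cycles).
    noise_sd
        Per-gene total SD (cycles); must be >= ``sample_sd`` for every gene
        so the shared sample effect fits inside the marginal variance.
    groups
        Ordered group labels.
    group_shift
        gene -> {group -> shift in cycles}; missing entries are 0.
    sample_sd
        SD (cycles) of the per-sample effect shared across all genes.
    couplings
        gene -> Pearson coupling coefficient in [0, 1] against
        ``target_gene``.
    target_gene
        Gene receiving the full latent loading when couplings are present.
    replicates
        Biological replicates per group (>= 2).
    seed
        Default RNG seed; ``simulate_ct`` may override it.
    """

    baseline_ct: dict[str, float]
    noise_sd: dict[str, float]
    groups: list[str]
    group_shift: dict[str, dict[str, float]] = field(default_factory=dict)
    sample_sd: float = 0.1
    couplings: dict[str, float] = field(default_factory=dict)
    target_gene: str | None = None
    replicates: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.replicates < 2:
            raise ValueError("replicates must be >= 2")
        if self.sample_sd < 0:
            raise ValueError("sample_sd must be >= 0")
        if set(self.noise_sd) != set(self.baseline_ct):
            raise ValueError("noise_sd and baseline_ct must cover the same genes")
        for gene, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"negative SD for {gene!r}")
            if sd < self.sample_sd:
                raise ValueError(
                    f"gene {gene!r}: total SD {sd} smaller than sample_sd "
                    f"{self.sample_sd}; the shared effect cannot fit"
                )
        for gene, c in self.couplings.items():
            if not 0.0 <= c <= 1.0:
                raise ValueError(f"coupling for {gene!r} must be in [0, 1]")
            if self.target_gene is None:
                raise ValueError("couplings require a target_gene")
        for gene, shifts in self.group_shift.items():
            unknown = set(shifts) - set(self.groups)
            if unknown:
                raise ValueError(f"group_shift for {gene!r} names unknown groups {unknown}")

    @property
    def genes(self) -> list[str]:
        return list(self.baseline_ct)

    @classmethod
    def from_json(cls, path: str | Path) -> "SimulationConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


@dataclass
class TruthRecord:
    """Realized generator parameters, kept for recovery scoring."""

    baseline_ct: dict[str, float]
    noise_sd: dict[str, float]
    group_shift: dict[str, dict[str, float]]
    sample_sd: float
    couplings: dict[str, float]
    latent_loadings: dict[str, float]
    seed: int | None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2)


def _latent_loadings(config: SimulationConfig) -> dict[str, float]:
    """Solve each coupled gene's latent loading from its target coupling."""
    loadings: dict[str, float] = {}
    if not config.couplings:
        return loadings
    target = config.target_gene
    sd_t = config.noise_sd[target]
    sb2 = config.sample_sd**2
    resid_t = np.sqrt(max(sd_t**2 - sb2, 0.0))
    loadings[target] = 1.0
    for gene, c in config.couplings.items():
        if gene == target:
            continue
        sd_g = config.noise_sd[gene]
        resid_g = np.sqrt(max(sd_g**2 - sb2, 0.0))
        denom = resid_g * resid_t
        if denom == 0:
            loadings[gene] = 0.0
            continue
        loadings[gene] = float(np.clip((c * sd_g * sd_t - sb2) / denom, 0.0, 1.0))
    return loadings


def simulate_ct(
    config: SimulationConfig, seed: int | None = None
) -> tuple[CtTable, TruthRecord]:
    """Draw one synthetic Ct table; deterministic for a fixed seed.

    Sample ids are ``<group>_<replicate>`` in group-major order.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    genes = config.genes
    n = config.replicates * len(config.groups)
    sample_ids = [f"{g}_{i + 1}" for g in config.groups for i in range(config.replicates)]
    group_of = pd.Series(
        [g for g in config.groups for _ in range(config.replicates)], index=sample_ids
    )

    loadings = _latent_loadings(config)
    b = rng.normal(0.0, config.sample_sd, size=n) if config.sample_sd > 0 else np.zeros(n)
    u = rng.standard_normal(n)

    ct = pd.DataFrame(index=pd.Index(sample_ids, name="sample"), columns=genes, dtype=float)
    sb2 = config.sample_sd**2
    for gene in genes:
        sd = config.noise_sd[gene]
        resid = np.sqrt(max(sd**2 - sb2, 0.0))
        load = loadings.get(gene, 0.0)
        z = rng.standard_normal(n)
        shared = resid * (load * u + np.sqrt(max(1.0 - load**2, 0.0)) * z)
        shifts = config.group_shift.get(gene, {})
        shift = group_of.map(lambda grp: shifts.get(grp, 0.0)).to_numpy(float)
        ct[gene] = config.baseline_ct[gene] + shift + b + shared

    table = CtTable(ct, group_of, config.target_gene)
    truth = TruthRecord(
        baseline_ct=dict(config.baseline_ct),
        noise_sd=dict(config.noise_sd),
        group_shift={g: dict(s) for g, s in config.group_shift.items()},
        sample_sd=config.sample_sd,
        couplings=dict(config.couplings),
        latent_loadings=loadings,
        seed=seed,
    )
    return table, truth


# Published descriptive moments of the six-candidate 3T3-L1 adipocyte panel:
# mean Ct and SD in cycles over 6 treatment groups x 6 replicates.
_PANEL_MEAN = {
    "18S": 14.52,
    "36B4": 18.72,
    "GAPDH": 17.11,
    "HMBS": 24.71,
    "HPRT": 23.14,
    "Actb": 18.47,
}
_PANEL_SD = {
    "18S": 0.31,
    "36B4": 0.20,
    "GAPDH": 0.21,
    "HMBS": 0.19,
    "HPRT": 0.16,
    "Actb": 0.33,
}
_GROUPS = ["IC", "MRS", "M2.1", "C8", "C15", "P4"]
_TARGET = "PPARG"
# PPARG is the highly regulated adipogenesis target: expressed ~7.5 cycles
# later than 18S and with markedly larger dispersion than the references.
_TARGET_MEAN = _PANEL_MEAN["18S"] + 7.5
_TARGET_SD = 0.75


def default_3t3l1_config(
    actb_coupling: float = 0.0,
    gapdh_shift: float = 0.0,
    sample_sd: float = 0.1,
    replicates: int = 6,
    seed: int | None = None,
) -> SimulationConfig:
    """Six-group, six-replicate 3T3-L1 adipocyte study design.

    Six candidate references (18S, 36B4, GAPDH, HMBS, HPRT, Actb) with
    their published per-gene mean Ct and cycle SD, plus the PPARG target
    7.5 cycles above 18S.  Optional stressors recreate the confounds the
    validation workflow is built to catch:

    - ``actb_coupling``: Pearson co-regulation of Actb with PPARG (actin
      remodelling accompanies adipogenic activation);
    - ``gapdh_shift``: +shift cycles applied to GAPDH in the four
      supernatant-treated groups (a treatment-responsive glycolytic gene).
    """
    shifts: dict[str, dict[str, float]] = {}
    if gapdh_shift:
        shifts["GAPDH"] = {g: gapdh_shift for g in ["M2.1", "C8", "C15", "P4"]}
    couplings = {"Actb": actb_coupling} if actb_coupling else {}
    return SimulationConfig(
        baseline_ct={**_PANEL_MEAN, _TARGET: _TARGET_MEAN},
        noise_sd={**_PANEL_SD, _TARGET: _TARGET_SD},
        groups=list(_GROUPS),
        group_shift=shifts,
        sample_sd=sample_sd,
        couplings=couplings,
        target_gene=_TARGET,
        replicates=replicates,
        seed=seed,
    )
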