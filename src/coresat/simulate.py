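"""Synthetic cohort generator with planted core/satellite structure.

Emulates a three-group faecal-amplicon study (one healthy control group and
two disease subtypes): high-prevalence core taxa whose mean percent
abundances are log-normally distributed, low-prevalence low-abundance
satellite taxa, a positive coupling between occupancy and log abundance, a
group-specific expansion of satellite relative abundance in the disease
groups, multinomial read sampling at a realistic depth, and a
taxon-to-pathway incidence structure containing some satellite-exclusive
pathways.  Every downstream stage is tested against the planted truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .io import CountMatrix

__all__ = ["SimulationConfig", "GroundTruth", "simulate_counts",
           "simulate_pathway_assignments"]


def _logit(p: float) -> float:
    return float(np.log(p / (1.0 - p)))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SimulationConfig:
    """Parameters of the planted cohort.

    Abundance parameters live on the log10 percent-abundance scale.  The
    first group is the control; ``disease_satellite_expansion`` multiplies
    the latent satellite abundances of every non-control group (scalar, or
    one multiplier per group with the control's equal to 1).
    """

    n_groups: int = 3
    samples_per_group: int = 12
    n_core: int = 40
    n_satellite: int = 160
    core_logmean: float = 0.0
    core_logsd: float = 0.5
    core_prevalence: float = 0.95
    satellite_prevalence: float = 0.3
    satellite_abundance_scale: float = 4.0
    disease_satellite_expansion: float | Sequence[float] = 2.0
    depth: int = 50_000
    da_slope: float = 1.5
    sample_logsd: float = 0.3
    overdispersion: float | None = None
    n_shared_pathways: int = 20
    n_exclusive_pathways: int = 5
    seed: int = 0
    group_names: Sequence[str] | None = None

    def __post_init__(self) -> None:
        if not (0.75 <= self.core_prevalence <= 1.0):
            raise ValueError("core_prevalence must lie in [0.75, 1]")
        if not (0.0 < self.satellite_prevalence < 0.75):
            raise ValueError("satellite_prevalence must lie in (0, 0.75)")
        if self.n_core + self.n_satellite < 2:
            raise ValueError("need at least two taxa")
        if self.depth < 10:
            raise ValueError("depth must be >= 10")
        if self.satellite_abundance_scale <= 0 or self.da_slope < 0:
            raise ValueError("satellite_abundance_scale and da_slope must be positive")
        if self.group_names is None:
            names = ["control"] + [f"disease_{i}" for i in range(1, self.n_groups)]
            self.group_names = names
        if len(self.group_names) != self.n_groups:
            raise ValueError("group_names length must equal n_groups")

    def expansion_by_group(self) -> np.ndarray:
        e = self.disease_satellite_expansion
        if np.isscalar(e):
            out = np.full(self.n_groups, float(e))
            out[0] = 1.0
        else:
            out = np.asarray(e, dtype=float)
            if len(out) != self.n_groups:
                raise ValueError("per-group expansion needs n_groups entries")
        if (out < 1.0).any():
            raise ValueError("expansion multipliers must be >= 1")
        return out


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort."""

    #: taxon x group DataFrame of labels in {"core", "satellite"}
    labels: pd.DataFrame
    #: pathway ids assigned exclusively to satellite taxa (filled by
    #: :func:`simulate_pathway_assignments`)
    satellite_exclusive_pathways: list[str] = field(default_factory=list)
    #: taxon -> set of pathway ids (filled by simulate_pathway_assignments)
    pathway_incidence: dict[str, list[str]] = field(default_factory=dict)

    def core_taxa(self) -> list[str]:
        return list(self.labels.index[(self.labels == "core").all(axis=1)])

    def satellite_taxa(self) -> list[str]:
        return list(self.labels.index[(self.labels == "satellite").all(axis=1)])


def simulate_counts(cfg: SimulationConfig) -> tuple[CountMatrix, GroundTruth]:
    """Draw a planted cohort; deterministic for a fixed ``cfg.seed``.

    Per taxon a latent mean log10 percent abundance is drawn (core:
    normal(core_logmean, core_logsd); satellite: the same shifted down by
    log10(satellite_abundance_scale)).  Presence probability couples to the
    latent log abundance through a logistic link centred on the class
    prevalence with slope ``da_slope``, producing the positive
    distribution-abundance relationship.  Per sample, presence is Bernoulli,
    abundance gets log-normal sample noise, disease groups multiply
    satellite abundances by their expansion factor, and reads are drawn
    multinomially at ``depth`` (or Dirichlet-multinomial when
    ``overdispersion`` is set).
    """
    rng = np.random.default_rng(cfg.seed)
    n_taxa = cfg.n_core + cfg.n_satellite
    taxa = [f"OTU{i:04d}" for i in range(1, n_taxa + 1)]
    is_core = np.array([i < cfg.n_core for i in range(n_taxa)])

    sat_shift = np.log10(cfg.satellite_abundance_scale)
    latent = rng.normal(cfg.core_logmean, cfg.core_logsd, size=n_taxa)
    latent[~is_core] -= sat_shift

    # logistic presence probability centred on the class prevalence at the
    # class-mean latent abundance; slope da_slope couples occupancy to
    # log10 abundance
    class_centre = np.where(is_core, cfg.core_logmean, cfg.core_logmean - sat_shift)
    base_logit = np.where(is_core, _logit(cfg.core_prevalence),
                          _logit(cfg.satellite_prevalence))
    presence_p = _sigmoid(base_logit + cfg.da_slope * (latent - class_centre))

    expansion = cfg.expansion_by_group()
    columns: dict[str, np.ndarray] = {}
    group_of: dict[str, str] = {}
    for g_idx, g_name in enumerate(cfg.group_names):
        for s_idx in range(cfg.samples_per_group):
            sid = f"{g_name}_s{s_idx + 1:02d}"
            present = rng.random(n_taxa) < presence_p
            if not present.any():
                present[int(np.argmax(latent))] = True
            abund = 10.0 ** (latent + rng.normal(0.0, cfg.sample_logsd, n_taxa))
            abund[~is_core] *= expansion[g_idx]
            abund = abund * present
            p = abund / abund.sum()
            if cfg.overdispersion is not None:
                alpha = p[present] * cfg.overdispersion
                p_pos = rng.dirichlet(alpha)
                p = np.zeros(n_taxa)
                p[present] = p_pos
            columns[sid] = rng.multinomial(cfg.depth, p)
            group_of[sid] = g_name

    counts = pd.DataFrame(columns, index=taxa)
    counts.index.name = "taxon_id"
    groups = pd.Series(group_of, name="group")
    labels = pd.DataFrame(
        {g: np.where(is_core, "core", "satellite") for g in cfg.group_names},
        index=taxa,
    )
    m = CountMatrix(counts, groups)
    # keep truth rows only for taxa that survived sampling
    return m, GroundTruth(labels.loc[m.taxon_ids])


def simulate_pathway_assignments(
    cfg: SimulationConfig, truth: GroundTruth, m: CountMatrix
) -> pd.DataFrame:
    """Plant a taxon-to-pathway incidence and emit per-sample contributions.

    ``n_shared_pathways`` pathways are assigned to random taxa from the whole
    community; ``n_exclusive_pathways`` pathways are assigned only to
    satellite taxa.  Each (sample, taxon, pathway) contribution equals the
    taxon's read count in that sample (binary incidence weights), so
    per-sample pathway totals are exact sums of contributing counts.
    Returns the long-form contribution table and records the planted
    exclusive ids on ``truth``.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    taxa = np.array(m.taxon_ids)
    sat = np.array([t for t in taxa if (truth.labels.loc[t] == "satellite").all()])
    n_total = cfg.n_shared_pathways + cfg.n_exclusive_pathways
    width = max(3, len(str(n_total)))
    incidence: dict[str, list[str]] = {t: [] for t in taxa}
    exclusive: list[str] = []
    for i in range(cfg.n_shared_pathways):
        pid = f"P{i + 1:0{width}d}"
        members = taxa[rng.random(len(taxa)) < 0.3]
        if len(members) == 0:
            members = taxa[[rng.integers(len(taxa))]]
        for t in members:
            incidence[t].append(pid)
    for i in range(cfg.n_exclusive_pathways):
        pid = f"P{cfg.n_shared_pathways + i + 1:0{width}d}"
        members = sat[rng.random(len(sat)) < 0.2]
        if len(members) == 0:
            members = sat[[rng.integers(len(sat))]]
        for t in members:
            incidence[t].append(pid)
        exclusive.append(pid)

    records = []
    counts = m.counts
    for t in taxa:
        if not incidence[t]:
            continue
        row = counts.loc[t]
        pos = row[row > 0]
        for sid, cnt in pos.items():
            for pid in incidence[t]:
                records.append((sid, t, pid, float(cnt)))
    contrib = pd.DataFrame(
        records, columns=["sample_id", "taxon_id", "function_id", "abundance"]
    )
    truth.satellite_exclusive_pathways = exclusive
    truth.pathway_incidence = {t: sorted(v) for t, v in incidence.items() if v}
    return contrib
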