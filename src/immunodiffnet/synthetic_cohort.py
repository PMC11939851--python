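"""Seeded synthetic cohorts with planted statistical structure.

The study cohort this emulates: 27 metastatic NSCLC patients profiled
before anti-PD1 therapy for 13 soluble immune checkpoints, 18 circulating
cytokines/chemokines/adhesion molecules (all pg/mL) and 3 CD137+ T-cell
subsets (percent of parent population), annotated with response (14 R /
13 NR at 6 months), ECOG performance status (15 PS=0 / 12 PS>0) and an
overall-survival dichotomy at 3 months (21 > 3 / 6 <= 3, the early
progressors). Those margins are the generator's defaults.

Values are sampled on a latent Gaussian scale, where condition-specific
correlation blocks are planted, then mapped through exp() to positive,
right-skewed lognormal concentrations (Luminex-like). Planting on the
latent scale means observed-scale Pearson correlations are mildly
attenuated relative to the nominal block rho; the analysis pipeline's
log step largely undoes the warp. Optional extras: a small patient
cluster with elevated levels on chosen markers, and outlier patients
shifted on every marker (to exercise dendrogram-based outlier removal).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_io import (
    STANDARD_CONTRASTS,
    ClinicalTable,
    ImmuneProfileMatrix,
)
from .errors import ConfigError

__all__ = ["PlantedBlock", "PlantedCluster", "PlantedOutliers",
           "SyntheticCohortConfig", "GroundTruth", "default_panel",
           "generate_cohort", "emulate_paper_margins"]


# ---------------------------------------------------------------------------
# default marker panel
# ---------------------------------------------------------------------------

_CHECKPOINTS = ["sBTLA", "sGITR", "sIDO", "sLAG3", "sPD1", "sPD-L1", "sPD-L2",
                "sTIM3", "sCD28", "sCD80", "sCD137", "sCD27", "sCTLA4"]
_CYTOKINES = ["sE-Selectin", "ICAM", "IFNa", "IFNg", "IL1a", "IL1b", "IL4",
              "IL6", "IL8", "IL10", "IL12", "IL13", "IL17", "IP10", "CCL2",
              "CCL4", "sP-Selectin", "TNFa"]
_CELL_SUBSETS = ["CD3+CD137+", "CD8+CD137+", "CD4+CD137+"]


def default_panel() -> dict[str, str]:
    """The 34-marker default panel: 13 checkpoints, 18 cytokines/chemokines/
    adhesion molecules, 3 CD137+ T-cell subsets."""
    panel: dict[str, str] = {}
    panel.update({m: "checkpoint" for m in _CHECKPOINTS})
    panel.update({m: "cytokine" for m in _CYTOKINES})
    panel.update({m: "cell_subset" for m in _CELL_SUBSETS})
    return panel


# latent log-scale location/spread per marker kind; chosen so back-transformed
# medians land in a plausible range (checkpoints/cytokines ~ 1e2-1e3 pg/mL,
# CD137+ subsets ~ 1% of parent)
_KIND_LOG_LOC = {"checkpoint": 5.5, "cytokine": 4.0, "cell_subset": 0.0}
_KIND_LOG_SCALE = {"checkpoint": 1.0, "cytokine": 1.0, "cell_subset": 0.7}


# ---------------------------------------------------------------------------
# config
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedBlock:
    """A marker set whose latent correlation is ``rho`` pairwise, active only
    for patients in ``condition`` of ``contrast`` (identity elsewhere)."""

    markers: tuple[str, ...]
    contrast: str           # response | performance_status | os_group
    condition: str          # label within that contrast, e.g. "NR"
    rho: float

    def __post_init__(self) -> None:
        if not -1 < self.rho < 1:
            raise ConfigError("block rho must be in (-1, 1)")
        if len(self.markers) < 2:
            raise ConfigError("a block needs at least 2 markers")
        k = len(self.markers)
        # equicorrelation matrix is positive definite iff rho > -1/(k-1)
        if self.rho <= -1.0 / (k - 1):
            raise ConfigError(
                f"equicorrelated block of {k} markers requires rho > "
                f"{-1.0 / (k - 1):.3f} for positive definiteness")


@dataclass(frozen=True)
class PlantedCluster:
    """A subgroup of patients with a mean shift (latent sd units) on a
    marker set — emulates a small cluster with elevated levels."""

    markers: tuple[str, ...]
    n_patients: int
    shift_sd: float


@dataclass(frozen=True)
class PlantedOutliers:
    """Patients shifted on *all* markers, detectable as dendrogram
    outliers."""

    count: int
    shift_sd: float = 8.0


@dataclass(frozen=True)
class SyntheticCohortConfig:
    n_patients: int = 27
    panel: dict[str, str] = field(default_factory=default_panel)
    response_margin: tuple[int, int] = (14, 13)       # (R, NR)
    ps_margin: tuple[int, int] = (15, 12)             # (PS0, PSgt0)
    os_margin: tuple[int, int] = (21, 6)              # (gt_cutoff, le_cutoff)
    os_cutoff_months: float = 3.0
    planted_blocks: tuple[PlantedBlock, ...] = ()
    planted_cluster: PlantedCluster | None = None
    planted_outliers: PlantedOutliers | None = None
    noise_sd: float = 1.0
    joint_margins: dict | None = None  # optional: variable -> patient -> label

    def __post_init__(self) -> None:
        for name, margin in (("response", self.response_margin),
                             ("ps", self.ps_margin), ("os", self.os_margin)):
            if sum(margin) != self.n_patients:
                raise ConfigError(
                    f"{name} margin {margin} does not sum to n_patients "
                    f"{self.n_patients}")
        for b in self.planted_blocks:
            missing = [m for m in b.markers if m not in self.panel]
            if missing:
                raise ConfigError(f"block markers not in panel: {missing}")
        if self.planted_cluster:
            missing = [m for m in self.planted_cluster.markers
                       if m not in self.panel]
            if missing:
                raise ConfigError(f"cluster markers not in panel: {missing}")
            if self.planted_cluster.n_patients > self.n_patients:
                raise ConfigError("planted cluster larger than cohort")
        if self.planted_outliers and self.planted_outliers.count > self.n_patients:
            raise ConfigError("more outliers than patients")


@dataclass
class GroundTruth:
    """What was planted: every differential pair with its expected edge
    class under the standard (adverse condition = A) contrast orientation,
    plus cluster/outlier patient ids."""

    planted_pairs: list[dict] = field(default_factory=list)
    cluster_patients: list[str] = field(default_factory=list)
    outlier_patients: list[str] = field(default_factory=list)

    def pairs_for(self, contrast: str) -> set[frozenset]:
        return {frozenset((d["marker_i"], d["marker_j"]))
                for d in self.planted_pairs if d["contrast"] == contrast}


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def emulate_paper_margins(cfg: SyntheticCohortConfig, seed: int) -> ClinicalTable:
    """Assign clinical labels matching the configured margins.

    Default: each variable is assigned independently by a seeded shuffle.
    With ``cfg.joint_margins`` set, the given per-patient labels are used
    verbatim (joint-table mode). os_months are drawn consistently with the
    assigned os_group.
    """
    rng = np.random.default_rng(seed)
    patients = [f"P{i + 1:02d}" for i in range(cfg.n_patients)]

    def assign(margin, labels):
        arr = np.array([labels[0]] * margin[0] + [labels[1]] * margin[1])
        rng.shuffle(arr)
        return arr

    table = pd.DataFrame(index=pd.Index(patients, name="patient_id"))
    if cfg.joint_margins is not None:
        for var in ("response", "performance_status", "os_group"):
            if var not in cfg.joint_margins:
                raise ConfigError(f"joint_margins missing variable {var!r}")
            col = pd.Series(cfg.joint_margins[var])
            missing = [p for p in patients if p not in col.index]
            if missing:
                raise ConfigError(f"joint_margins missing patients: {missing}")
            table[var] = col.loc[patients].to_numpy()
    else:
        table["response"] = assign(cfg.response_margin, ("R", "NR"))
        table["performance_status"] = assign(cfg.ps_margin, ("PS0", "PSgt0"))
        table["os_group"] = assign(cfg.os_margin, ("gt_cutoff", "le_cutoff"))

    cut = cfg.os_cutoff_months
    le = table["os_group"] == "le_cutoff"
    months = np.where(le,
                      rng.uniform(0.25, cut, cfg.n_patients),
                      rng.uniform(cut + 0.1, cut + 33.0, cfg.n_patients))
    table["os_months"] = np.round(months, 1)
    return ClinicalTable(table=table, os_cutoff_months=cut)


def _active_blocks(cfg: SyntheticCohortConfig, clin_row: pd.Series) -> tuple[int, ...]:
    """Indices of planted blocks active for one patient's labels."""
    return tuple(i for i, b in enumerate(cfg.planted_blocks)
                 if clin_row[STANDARD_CONTRASTS[b.contrast].column] == b.condition)


def generate_cohort(cfg: SyntheticCohortConfig, seed: int,
                    ) -> tuple[ImmuneProfileMatrix, ClinicalTable, GroundTruth]:
    """Draw one cohort: latent MVN per patient (identity correlation except
    planted blocks active for that patient's labels), exp back-transform to
    positive concentrations, planted-cluster and outlier mean shifts."""
    rng = np.random.default_rng(seed)
    clin = emulate_paper_margins(cfg, int(rng.integers(2**31)))
    markers = list(cfg.panel)
    m_index = {m: i for i, m in enumerate(markers)}
    n_m = len(markers)
    patients = clin.patient_ids

    # group patients by their set of active blocks; one Cholesky per group
    groups: dict[tuple[int, ...], list[str]] = {}
    for p in patients:
        groups.setdefault(_active_blocks(cfg, clin.table.loc[p]), []).append(p)

    latent = pd.DataFrame(0.0, index=markers, columns=patients)
    for active, members in groups.items():
        corr = np.eye(n_m)
        for bi in active:
            block = cfg.planted_blocks[bi]
            idx = [m_index[m] for m in block.markers]
            for a in idx:
                for b in idx:
                    if a != b:
                        if corr[a, b] not in (0.0, block.rho):
                            raise ConfigError(
                                "overlapping planted blocks disagree on a "
                                "pairwise correlation")
                        corr[a, b] = block.rho
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError as exc:
            raise ConfigError("requested correlation matrix is not positive "
                              "definite") from exc
        draws = rng.standard_normal((len(members), n_m)) @ chol.T
        latent[members] = (draws.T * cfg.noise_sd)

    truth = GroundTruth()
    for block in cfg.planted_blocks:
        contrast = STANDARD_CONTRASTS[block.contrast]
        side = "A" if block.condition == contrast.condition_A_label else "B"
        sym = "+" if block.rho > 0 else "-"
        cls = f"{sym}/0" if side == "A" else f"0/{sym}"
        ms = sorted(block.markers, key=m_index.get)
        for i in range(len(ms)):
            for j in range(i + 1, len(ms)):
                truth.planted_pairs.append({
                    "marker_i": ms[i], "marker_j": ms[j],
                    "contrast": block.contrast, "condition": block.condition,
                    "rho": block.rho, "expected_class": cls,
                })

    # planted cluster: elevated levels on selected markers for a patient subset
    free = list(patients)
    if cfg.planted_cluster:
        pc = cfg.planted_cluster
        chosen = [str(p) for p in rng.choice(free, size=pc.n_patients,
                                             replace=False)]
        latent.loc[list(pc.markers), chosen] += pc.shift_sd * cfg.noise_sd
        truth.cluster_patients = sorted(chosen)
        free = [p for p in free if p not in chosen]

    if cfg.planted_outliers:
        po = cfg.planted_outliers
        pool = free if len(free) >= po.count else list(patients)
        chosen = [str(p) for p in rng.choice(pool, size=po.count,
                                             replace=False)]
        # independent sign pattern per outlier so outliers do not form a
        # tight mutual cluster (they must appear as dendrogram singletons)
        signs = rng.choice([-1.0, 1.0], size=(n_m, po.count))
        latent[chosen] += po.shift_sd * cfg.noise_sd * signs
        truth.outlier_patients = sorted(chosen)

    loc = np.array([_KIND_LOG_LOC[cfg.panel[m]] for m in markers])[:, None]
    scale = np.array([_KIND_LOG_SCALE[cfg.panel[m]] for m in markers])[:, None]
    values = np.exp(loc + scale * latent.to_numpy())
    profiles = ImmuneProfileMatrix(
        values=pd.DataFrame(values, index=markers, columns=patients),
        marker_kinds=dict(cfg.panel), transform_state="raw")
    return profiles, clin, truth
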