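"""Synthetic microarray experiments for the adenoma-carcinoma pipeline.

The generator emulates the statistical structure the downstream analysis
assumes in bulk colorectal expression data:

* log-normal baseline intensities with heterogeneous per-probe biological
  variability, so a fold-change-versus-median filter separates stable from
  variable probes rather than sampling noise tails;
* two normalization-sensitive technical artifacts — a per-array
  multiplicative scale factor (log-normal) and a smooth intensity-dependent
  rank distortion (per-array power transform of the linear intensities);
* sex-labelled samples with Y-linked probes expressed only in males, so a
  detection threshold can be anchored at a percentile of female Y-probe
  signal;
* planted differentially expressed pathways between disease groups, with the
  group effect scaled by each sample's epithelium (tumor-cell) fraction so
  low-purity tumors drift toward the normal group;
* a cell-type mixture axis: every probe carries an epithelium-affinity
  coefficient multiplied by the sample's epithelium fraction, reproducing the
  epithelium-versus-mucosa confound that motivates background subtraction;
* probes with monotone NC -> AD -> CA expression trends (progression
  markers).

Every planted signal is recorded in a :class:`GroundTruth` so recovery can be
scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PlantedPathway",
    "SimulationDesign",
    "GroundTruth",
    "generate_pathway_dictionary",
    "probe_annotation",
    "simulate_experiment",
    "summarize_cell_composition",
    "reference_composition_table",
]

#: contrast label that plants an epithelium-affinity (cell-type) effect
#: instead of a disease-group effect.
EPITHELIUM_CONTRAST = "epithelium"


@dataclass(frozen=True)
class PlantedPathway:
    """A pathway with a planted expression signal.

    ``contrast`` is either ``"<base>_vs_<elevated>"`` (elevated may pool
    groups with ``+``, e.g. ``"NC_vs_AD+CA"``), in which case members gain
    ``log2_effect`` in the elevated groups, or :data:`EPITHELIUM_CONTRAST`,
    in which case members get an epithelium-affinity coefficient of
    ``log2_effect`` (log2 units per unit epithelium fraction).
    """

    pathway_id: str
    contrast: str
    log2_effect: float

    def elevated_groups(self) -> tuple[str, ...]:
        if self.contrast == EPITHELIUM_CONTRAST:
            return ()
        try:
            _base, elevated = self.contrast.split("_vs_")
        except ValueError:
            raise ValueError(f"malformed contrast name: {self.contrast!r}") from None
        return tuple(elevated.split("+"))


@dataclass
class SimulationDesign:
    """Parameters of one synthetic experiment.

    ``n_samples_per_group`` keys are sample-group labels; planted disease
    effects are keyed by *effect groups* (NC/AD/CA) and a sample group is
    mapped onto its effect group through ``group_effect_map`` (identity by
    default, with NT treated as NC).  Microdissected designs use composite
    sample groups such as ``CEC_AD`` mapped onto effect group ``AD``.
    """

    n_probes: int = 5000
    n_samples_per_group: Mapping[str, int] = field(
        default_factory=lambda: {"NC": 20, "AD": 20, "CA": 20}
    )
    n_pathways: int = 100
    pathway_size_range: tuple[int, int] = (10, 40)
    planted_pathways: tuple[PlantedPathway, ...] = ()
    n_monotone_up: int = 10
    n_monotone_down: int = 10
    monotone_step: float = 1.0
    monotone_group_order: tuple[str, str, str] = ("NC", "AD", "CA")
    monotone_up_ids: tuple[str, ...] | None = None
    monotone_down_ids: tuple[str, ...] | None = None
    y_probe_count: int = 30
    male_fraction: float = 0.5
    array_scale_sd: float = 0.15
    rank_distortion: float = 0.03
    epithelium_fraction_by_group: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"NC": (14, 6), "AD": (10, 10), "CA": (9, 11)}
    )
    epithelium_affinity_sd: float = 0.3
    group_effect_map: Mapping[str, str] | None = None
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.5
    background_log2: float = 4.0
    noise_sd: float = 0.2
    biological_sd_max: float = 0.4
    #: scale planted group effects by epithelium fraction relative to the
    #: group mean.  Appropriate for whole-tissue sections, where the tumor
    #: program is diluted by stromal admixture; microdissected samples have
    #: capture-controlled composition and carry the full effect.
    scale_effects_by_purity: bool = True
    handling_arm: str = "whole"
    seed: int = 0

    def effect_group(self, group: str) -> str:
        if self.group_effect_map and group in self.group_effect_map:
            return self.group_effect_map[group]
        if group == "NT":
            return "NC"
        return group

    def validate(self) -> None:
        if self.n_probes < 1:
            raise ValueError("n_probes must be >= 1")
        if not self.n_samples_per_group:
            raise ValueError("at least one sample group is required")
        for g, n in self.n_samples_per_group.items():
            if n < 1:
                raise ValueError(f"group {g!r} needs >= 1 sample")
            if g not in self.epithelium_fraction_by_group:
                raise ValueError(f"no epithelium Beta parameters for group {g!r}")
        if self.y_probe_count >= self.n_probes:
            raise ValueError("y_probe_count must be smaller than n_probes")
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        if self.array_scale_sd < 0 or self.rank_distortion < 0 or self.noise_sd <= 0:
            raise ValueError("scale/distortion sds must be >= 0, noise_sd > 0")
        for pp in self.planted_pathways:
            if not np.isfinite(pp.log2_effect):
                raise ValueError(f"non-finite effect for {pp.pathway_id}")
            pp.elevated_groups()  # validates the contrast name


@dataclass
class GroundTruth:
    """Everything the generator planted, for downstream recovery scoring."""

    de_probe_ids: dict[str, list[str]]
    planted_pathway_ids: dict[str, list[str]]
    monotone_up_ids: list[str]
    monotone_down_ids: list[str]
    array_scale: dict[str, float]
    epithelium_fraction: dict[str, float]

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# probe universe and pathway dictionary

def probe_ids(n_probes: int) -> list[str]:
    width = max(5, len(str(n_probes)))
    return [f"P{i:0{width}d}" for i in range(1, n_probes + 1)]


def probe_annotation(design: SimulationDesign) -> pd.DataFrame:
    """Probe -> gene symbol table with the trailing probes flagged Y-linked."""
    probes = probe_ids(design.n_probes)
    genes = [p.replace("P", "G", 1) for p in probes]
    is_y = np.zeros(design.n_probes, dtype=int)
    if design.y_probe_count:
        is_y[-design.y_probe_count:] = 1
    return pd.DataFrame(
        {"gene_symbol": genes, "is_chrY": is_y},
        index=pd.Index(probes, name="probe_id"),
    )


def generate_pathway_dictionary(
    n_pathways: int,
    size_range: tuple[int, int],
    universe: Sequence[str],
    overlap_fraction: float = 0.2,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Draw ``n_pathways`` gene sets over ``universe``.

    A fraction ``1 - overlap_fraction`` of each set is drawn from a pool used
    by no other set (until the pool runs out), the rest uniformly from the
    whole universe, giving KEGG-like partially overlapping flat categories.
    Deterministic for a fixed seed; members are sorted within each set.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    lo, hi = size_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid size range")
    if hi > len(universe):
        raise ValueError("max pathway size exceeds universe size")
    if not 0.0 <= overlap_fraction <= 1.0:
        raise ValueError("overlap_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    universe = list(universe)
    pool = list(rng.permutation(universe))
    sets: dict[str, list[str]] = {}
    width = max(3, len(str(n_pathways)))
    for i in range(1, n_pathways + 1):
        size = int(rng.integers(lo, hi + 1))
        n_unique = int(round(size * (1.0 - overlap_fraction)))
        members: set[str] = set()
        while pool and len(members) < n_unique:
            members.add(pool.pop())
        while len(members) < size:
            members.add(universe[int(rng.integers(len(universe)))])
        sets[f"PW{i:0{width}d}"] = sorted(members)
    return sets


# ---------------------------------------------------------------------------
# experiment simulation

def _member_probe_indices(
    pathway_id: str,
    dictionary: Mapping[str, Sequence[str]],
    annot: pd.DataFrame,
) -> np.ndarray:
    if pathway_id not in dictionary:
        raise ValueError(f"planted pathway {pathway_id!r} absent from dictionary")
    genes = set(dictionary[pathway_id])
    mask = annot["gene_symbol"].isin(genes).to_numpy()
    return np.flatnonzero(mask)


def simulate_experiment(
    design: SimulationDesign,
    dictionary: Mapping[str, Sequence[str]],
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one experiment.

    Returns the probe x sample intensity matrix (linear scale), the sample
    annotation table and the ground truth.  On the log2 scale a value is

        base_p + effect_{p,g(s)} * purity_s + affinity_p * (epi_s - 0.5) + noise

    where ``purity_s`` is the sample's epithelium fraction divided by its
    group's expected fraction (so the planted group-mean effect is unbiased
    but low-purity tumors carry attenuated effects).  The linear intensity is
    then taken through a per-array power transform (rank distortion) and
    multiplied by a per-array log-normal scale factor.  Y-linked probes are
    forced to background level (plus small noise) in female samples.
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    annot = probe_annotation(design)
    probes = annot.index.to_numpy()
    P = design.n_probes
    y_idx = np.flatnonzero(annot["is_chrY"].to_numpy() == 1)

    # --- samples
    sample_ids: list[str] = []
    groups: list[str] = []
    for g, n in design.n_samples_per_group.items():
        for i in range(1, n + 1):
            sample_ids.append(f"{g}_{i:02d}")
            groups.append(g)
    n_samples = len(sample_ids)
    sex = np.where(rng.random(n_samples) < design.male_fraction, "M", "F")
    epi = np.empty(n_samples)
    expected_epi = np.empty(n_samples)
    for j, g in enumerate(groups):
        a, b = design.epithelium_fraction_by_group[g]
        epi[j] = rng.beta(a, b)
        expected_epi[j] = a / (a + b)
    purity = epi / expected_epi if design.scale_effects_by_purity else np.ones(n_samples)

    # --- per-probe parameters
    base = rng.normal(design.baseline_log2_mean, design.baseline_log2_sd, P)
    affinity = rng.normal(0.0, design.epithelium_affinity_sd, P)
    bio_sd = rng.uniform(0.0, design.biological_sd_max, P)
    probe_sd = np.sqrt(design.noise_sd**2 + bio_sd**2)

    # --- planted pathway effects, keyed by effect group
    effect_groups = sorted({design.effect_group(g) for g in groups})
    for g in design.monotone_group_order:
        if g not in effect_groups:
            effect_groups.append(g)
    effect = {g: np.zeros(P) for g in effect_groups}
    planted_member_idx: set[int] = set()
    de_probe_ids: dict[str, list[str]] = {}
    planted_pathway_ids: dict[str, list[str]] = {}
    for pp in design.planted_pathways:
        idx = _member_probe_indices(pp.pathway_id, dictionary, annot)
        planted_member_idx.update(idx.tolist())
        planted_pathway_ids.setdefault(pp.contrast, []).append(pp.pathway_id)
        if pp.contrast == EPITHELIUM_CONTRAST:
            affinity[idx] = pp.log2_effect
        else:
            for g in pp.elevated_groups():
                if g not in effect:
                    raise ValueError(
                        f"contrast {pp.contrast!r} names unknown group {g!r}"
                    )
                effect[g][idx] += pp.log2_effect
        de_probe_ids.setdefault(pp.contrast, [])
        de_probe_ids[pp.contrast] = sorted(
            set(de_probe_ids[pp.contrast]) | set(probes[idx])
        )

    # --- monotone progression markers (disjoint from planted members and Y)
    eligible = np.setdiff1d(
        np.arange(P - design.y_probe_count), np.fromiter(planted_member_idx, int, len(planted_member_idx))
    )
    n_mono = design.n_monotone_up + design.n_monotone_down
    if design.monotone_up_ids is None or design.monotone_down_ids is None:
        if n_mono > len(eligible):
            raise ValueError("not enough probes free of planted effects for monotone markers")
        chosen = rng.choice(eligible, size=n_mono, replace=False)
        up_idx = np.sort(chosen[: design.n_monotone_up])
        down_idx = np.sort(chosen[design.n_monotone_up:])
    else:
        pos = {p: i for i, p in enumerate(probes)}
        up_idx = np.array(sorted(pos[p] for p in design.monotone_up_ids), dtype=int)
        down_idx = np.array(sorted(pos[p] for p in design.monotone_down_ids), dtype=int)
        if set(up_idx) & set(down_idx):
            raise ValueError("monotone up/down sets overlap")
    for level, g in enumerate(design.monotone_group_order):
        effect[g][up_idx] += level * design.monotone_step
        effect[g][down_idx] -= level * design.monotone_step

    # --- assemble log2 matrix
    log2 = np.empty((P, n_samples))
    for j, g in enumerate(groups):
        eg = design.effect_group(g)
        log2[:, j] = (
            base
            + effect[eg] * purity[j]
            + affinity * (epi[j] - 0.5)
            + rng.normal(0.0, 1.0, P) * probe_sd
        )
    # Y-linked probes sit at background in females
    female = np.flatnonzero(sex == "F")
    if len(y_idx) and len(female):
        log2[np.ix_(y_idx, female)] = design.background_log2 + rng.normal(
            0.0, 0.3, (len(y_idx), len(female))
        )

    # --- technical artifacts on the linear scale
    gamma = rng.normal(0.0, design.rank_distortion, n_samples)
    scale = np.exp(rng.normal(0.0, design.array_scale_sd, n_samples))
    intensities = np.exp2(log2 * (1.0 + gamma)[None, :]) * scale[None, :]

    matrix = pd.DataFrame(
        intensities, index=pd.Index(probes, name="probe_id"), columns=sample_ids
    )
    sample_annot = pd.DataFrame(
        {
            "group": groups,
            "sex": sex,
            "arm": design.handling_arm,
            "tumor_content_percent": np.round(epi * 100.0, 1),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    truth = GroundTruth(
        de_probe_ids=de_probe_ids,
        planted_pathway_ids=planted_pathway_ids,
        monotone_up_ids=list(probes[up_idx]),
        monotone_down_ids=list(probes[down_idx]),
        array_scale={s: float(f) for s, f in zip(sample_ids, scale)},
        epithelium_fraction={s: float(e) for s, e in zip(sample_ids, epi)},
    )
    return matrix, sample_annot, truth


# ---------------------------------------------------------------------------
# cell composition summaries

def summarize_cell_composition(
    table: pd.DataFrame, epithelial_row: str = "Epithelial cells"
) -> pd.DataFrame:
    """Per-column total cell count and epithelial percentage.

    ``table`` holds cell counts per mm^2 with cell types on the index and
    tissue columns.  The epithelial percentage is rounded half-up to one
    decimal, matching how such histology tables are conventionally printed.
    """
    if epithelial_row not in table.index:
        raise ValueError(f"designated epithelial row {epithelial_row!r} missing")
    if (table.to_numpy() < 0).any():
        raise ValueError("cell counts must be >= 0")
    totals = table.sum(axis=0)
    if (totals == 0).any():
        bad = totals.index[totals == 0].tolist()
        raise ValueError(f"zero total cell count in column(s) {bad}: percent undefined")
    pct = [
        float(
            Decimal(str(100.0 * table.loc[epithelial_row, c] / totals[c])).quantize(
                Decimal("0.1"), rounding=ROUND_HALF_UP
            )
        )
        for c in table.columns
    ]
    return pd.DataFrame(
        {"total": totals.astype(int), "epithelial_percent": pct}, index=table.columns
    )


def reference_composition_table() -> pd.DataFrame:
    """Worked-example cell-type counts per mm^2 for colorectal tissue.

    Histology counts for normal colon, normal colon dissected from tumor,
    adenoma and carcinoma, used by the composition summary worked example.
    """
    data = {
        "Normal colon": [3183, 240, 266, 80, 594, 20, 47, 26],
        "Normal colon from tumor": [3032, 880, 420, 60, 173, 26, 40, 160],
        "Adenoma": [1650, 280, 765, 24, 133, 37, 78, 120],
        "Carcinoma": [2330, 133, 164, 31, 92, 35, 45, 33],
    }
    index = [
        "Epithelial cells",
        "Fibroblasts",
        "Lymphocytes",
        "Intraepithelial lymphocytes",
        "Plasmocytes",
        "Granulocytes",
        "Histocytes",
        "Endothelial cells",
    ]
    return pd.DataFrame(data, index=pd.Index(index, name="cell_type"))
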