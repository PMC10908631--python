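"""Synthetic tumor-tissue cohorts with planted spatial and marker structure.

This module generates per-cell tables, per-sample metadata and (optionally)
rendered label-mask / channel images that emulate segmented imaging
mass-cytometry data from a two-arm mouse experiment: non-treated tumors
(``NT``) versus locally irradiated tumors (``IT``).  The planted structure —
clustered neutrophil infiltrates in NT, treatment-dependent marker shifts
(e.g. E-Cadherin suppression in NT), and correlated survival / serum NET
readouts — gives every downstream analysis stage a known ground truth to
recover.

Cells are points carrying a stored area; they are rendered as pixel discs
only when images are requested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "PANEL",
    "CELL_TYPES",
    "GROUPS",
    "ClusterParams",
    "SurvivalModel",
    "GeneratorConfig",
    "GroundTruth",
    "SampleMetadata",
    "SampleResult",
    "Cohort",
    "default_marker_model",
    "simulate_sample",
    "simulate_cohort",
    "render_sample_images",
    "sample_background_levels",
]

#: The 19-marker antibody panel (antigen names).
PANEL: tuple[str, ...] = (
    "Aquaporin5",
    "Cytokeratin5",
    "CollagenI",
    "E-Cadherin",
    "Cytokeratin7",
    "Histone3",
    "Histone3Cit",
    "CD4",
    "CD8a",
    "CD3",
    "NeutrophilElastase",
    "DNA",
    "CD11b",
    "Ly6G",
    "Ki67",
    "pS6",
    "SMAD4",
    "TGFb1",
    "Slug",
)

#: Canonical cell-type order (alphabetical; used everywhere downstream).
CELL_TYPES: tuple[str, ...] = ("cd4t", "cd8t", "myeloid", "neutrophil", "tumor")

GROUPS: tuple[str, ...] = ("NT", "IT")

# log-space intensity levels for the default marker model
_HI = math.log(20.0)  # positive population
_LO = 0.0             # negative population
_DIM = math.log(1.6)  # weakly expressed / noise floor


def default_marker_model() -> dict[str, dict[str, tuple[float, float]]]:
    """Default type x marker lognormal model: ``marker -> type -> (mu, sigma)``.

    Only lineage markers (CD11b, Ly6G, CD3, CD4, CD8a), E-Cadherin, the DNA
    channel and the EMT-associated markers (TGFb1, SMAD4, Slug) carry
    cell-type structure; the remaining channels are pure noise.
    """
    sig = 0.4
    model: dict[str, dict[str, tuple[float, float]]] = {}
    for marker in PANEL:
        model[marker] = {t: (_DIM, sig) for t in CELL_TYPES}
    model["CD11b"].update(neutrophil=(_HI, sig), myeloid=(_HI, sig),
                          cd4t=(_LO, sig), cd8t=(_LO, sig), tumor=(_LO, sig))
    model["Ly6G"].update(neutrophil=(_HI, sig), myeloid=(_LO, sig),
                         cd4t=(_LO, sig), cd8t=(_LO, sig), tumor=(_LO, sig))
    model["CD3"].update(cd4t=(_HI, sig), cd8t=(_HI, sig),
                        neutrophil=(_LO, sig), myeloid=(_LO, sig), tumor=(_LO, sig))
    model["CD4"].update(cd4t=(_HI, sig),
                        cd8t=(_LO, sig), neutrophil=(_LO, sig),
                        myeloid=(_LO, sig), tumor=(_LO, sig))
    model["CD8a"].update(cd8t=(_HI, sig),
                         cd4t=(_LO, sig), neutrophil=(_LO, sig),
                         myeloid=(_LO, sig), tumor=(_LO, sig))
    model["E-Cadherin"].update(tumor=(_HI, sig))
    model["DNA"] = {t: (math.log(8.0), sig) for t in CELL_TYPES}
    model["SMAD4"].update(tumor=(math.log(4.0), sig))
    model["Slug"].update(tumor=(math.log(4.0), sig))
    model["TGFb1"] = {t: (math.log(3.0), sig) for t in CELL_TYPES}
    return model


@dataclass
class ClusterParams:
    """Thomas-type cluster process parameters for neutrophil infiltrates.

    ``n_clusters`` parent centers are placed uniformly in the ROI; each
    receives a Poisson(``cells_per_cluster``) number of offspring displaced
    by an isotropic Gaussian with standard deviation ``cluster_radius`` (µm).
    """

    n_clusters: int = 5
    cluster_radius: float = 20.0
    cells_per_cluster: float = 40.0


@dataclass
class SurvivalModel:
    """Group-wise exponential survival + serum NE-DNA readout.

    Survival times are exponential with group-specific ``hazard`` (1/day).
    Serum NE-DNA (ELISA absorbance units) is a linear function of the
    centered survival time plus Gaussian noise; ``correlation_sign`` sets
    the direction (default +1: higher serum NE-DNA with longer survival).
    """

    hazard: dict[str, float] = field(default_factory=lambda: {"NT": 1 / 21.0, "IT": 1 / 45.0})
    serum_mean: dict[str, float] = field(default_factory=lambda: {"NT": 1.2, "IT": 0.5})
    serum_sd: dict[str, float] = field(default_factory=lambda: {"NT": 0.1, "IT": 0.1})
    serum_survival_slope: float = 0.01
    correlation_sign: int = 1


@dataclass
class GeneratorConfig:
    """Full configuration of the synthetic cohort generator.

    Densities are base intensities in cells/µm²; the neutrophil density is
    the unclustered background on top of the group-specific cluster process.
    """

    roi_width: float = 600.0
    roi_height: float = 600.0
    densities: dict[str, float] = field(default_factory=lambda: {
        "tumor": 0.002,
        "myeloid": 0.0004,
        "cd4t": 0.00012,
        "cd8t": 0.00012,
        "neutrophil": 0.00005,
    })
    neutrophil_cluster_params: dict[str, ClusterParams] = field(default_factory=lambda: {
        "NT": ClusterParams(n_clusters=5, cluster_radius=20.0, cells_per_cluster=40.0),
        "IT": ClusterParams(n_clusters=1, cluster_radius=20.0, cells_per_cluster=40.0),
    })
    marker_model: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=default_marker_model)
    treatment_effects: dict[str, dict[str, float]] = field(default_factory=lambda: {
        "NT": {"E-Cadherin": 0.5, "DNA": 1.3, "SMAD4": 1.25, "Slug": 1.25},
        "IT": {},
    })
    survival_model: SurvivalModel = field(default_factory=SurvivalModel)
    area_log_mean: float = math.log(65.0)
    area_log_sd: float = 0.25
    background_fraction: float = 0.3
    max_cells: int = 50_000
    seed: int = 0

    def validate(self) -> None:
        if self.roi_width <= 0 or self.roi_height <= 0:
            raise ValueError("ROI dimensions must be positive")
        for t, d in self.densities.items():
            if d < 0:
                raise ValueError(f"density for {t!r} must be >= 0")
        for g, cp in self.neutrophil_cluster_params.items():
            if cp.cluster_radius <= 0:
                raise ValueError("cluster radius must be positive")
            if cp.cluster_radius >= min(self.roi_width, self.roi_height) / 2:
                raise ValueError("cluster radius must be < min(ROI dims)/2")
            if cp.n_clusters < 0 or cp.cells_per_cluster < 0:
                raise ValueError("cluster counts must be >= 0")
        for marker, per_type in self.marker_model.items():
            for t, (mu, sigma) in per_type.items():
                if sigma <= 0:
                    raise ValueError(f"sigma for {marker}/{t} must be > 0")

    def expected_cells(self, group: str) -> float:
        area = self.roi_width * self.roi_height
        n = sum(self.densities.get(t, 0.0) for t in CELL_TYPES) * area
        cp = self.neutrophil_cluster_params[group]
        return n + cp.n_clusters * cp.cells_per_cluster

    # --- serialization -------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "GeneratorConfig":
        d = dict(d)
        if "neutrophil_cluster_params" in d:
            d["neutrophil_cluster_params"] = {
                g: cp if isinstance(cp, ClusterParams) else ClusterParams(**cp)
                for g, cp in d["neutrophil_cluster_params"].items()}
        if "survival_model" in d and not isinstance(d["survival_model"], SurvivalModel):
            d["survival_model"] = SurvivalModel(**d["survival_model"])
        if "marker_model" in d:
            d["marker_model"] = {
                m: {t: tuple(v) for t, v in per.items()}
                for m, per in d["marker_model"].items()}
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "GeneratorConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """Planted truth for one sample: per-cell type and cluster membership."""

    table: pd.DataFrame  # cell_id, true_type, cluster_id (0 = background)
    applied_effects: dict[str, float]

    def type_counts(self) -> pd.Series:
        return self.table["true_type"].value_counts().reindex(CELL_TYPES, fill_value=0)


@dataclass
class SampleMetadata:
    sample_id: str
    group: str
    survival_time: float
    event: int
    serum_ne_dna: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SampleResult:
    cells: pd.DataFrame
    ground_truth: GroundTruth
    metadata: SampleMetadata


@dataclass
class Cohort:
    samples: list[SampleResult]
    config: GeneratorConfig

    @property
    def cells(self) -> pd.DataFrame:
        return pd.concat([s.cells for s in self.samples], ignore_index=True)

    @property
    def metadata(self) -> pd.DataFrame:
        return pd.DataFrame([s.metadata.to_dict() for s in self.samples])

    @property
    def ground_truth(self) -> pd.DataFrame:
        parts = []
        for s in self.samples:
            t = s.ground_truth.table.copy()
            t.insert(0, "sample_id", s.metadata.sample_id)
            parts.append(t)
        return pd.concat(parts, ignore_index=True)

    def groups(self) -> dict[str, str]:
        return {s.metadata.sample_id: s.metadata.group for s in self.samples}


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def simulate_sample(config: GeneratorConfig, group: str, seed,
                    sample_id: str | None = None) -> SampleResult:
    """Simulate one tissue sample.

    Tumor, myeloid and T cells follow homogeneous Poisson point processes;
    neutrophils follow a Thomas-type cluster process (a fixed number of
    uniform parent centers with Poisson offspring, Gaussian displacement)
    on top of a sparse uniform background.  Marker intensities are drawn
    from the type x marker lognormal model with multiplicative group
    effects.  Identical ``(config, group, seed)`` reproduce the output
    bit-exactly.
    """
    config.validate()
    if group not in GROUPS:
        raise ValueError(f"group must be one of {GROUPS}, got {group!r}")
    if config.expected_cells(group) > config.max_cells:
        raise ValueError("expected total cell count exceeds config.max_cells")
    rng = _as_rng(seed)
    w, h = config.roi_width, config.roi_height
    area = w * h

    xs, ys, types, cluster_ids = [], [], [], []
    for t in CELL_TYPES:
        lam = config.densities.get(t, 0.0) * area
        n = int(rng.poisson(lam)) if lam > 0 else 0
        if n:
            xs.append(rng.uniform(0, w, n))
            ys.append(rng.uniform(0, h, n))
            types.extend([t] * n)
            cluster_ids.append(np.zeros(n, dtype=int))
        if t == "neutrophil":
            cp = config.neutrophil_cluster_params[group]
            if cp.n_clusters > 0:
                px = rng.uniform(0, w, cp.n_clusters)
                py = rng.uniform(0, h, cp.n_clusters)
                for ci in range(cp.n_clusters):
                    m = int(rng.poisson(cp.cells_per_cluster))
                    if m == 0:
                        continue
                    ox = np.clip(px[ci] + rng.normal(0, cp.cluster_radius, m), 0, np.nextafter(w, 0))
                    oy = np.clip(py[ci] + rng.normal(0, cp.cluster_radius, m), 0, np.nextafter(h, 0))
                    xs.append(ox)
                    ys.append(oy)
                    types.extend(["neutrophil"] * m)
                    cluster_ids.append(np.full(m, ci + 1, dtype=int))

    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    cluster_id = np.concatenate(cluster_ids) if cluster_ids else np.empty(0, dtype=int)
    type_arr = np.array(types, dtype=object)
    n_cells = len(type_arr)

    areas = np.clip(rng.lognormal(config.area_log_mean, config.area_log_sd, n_cells),
                    10.0, 300.0)

    effects = dict(config.treatment_effects.get(group, {}))
    intensities = {}
    for marker in PANEL:
        per_type = config.marker_model[marker]
        mu = np.array([per_type[t][0] for t in type_arr], dtype=float) if n_cells else np.empty(0)
        sg = np.array([per_type[t][1] for t in type_arr], dtype=float) if n_cells else np.empty(0)
        vals = np.exp(rng.normal(mu, sg)) if n_cells else np.empty(0)
        vals *= effects.get(marker, 1.0)
        intensities[marker] = vals

    sm = config.survival_model
    t_surv = float(rng.exponential(1.0 / sm.hazard[group]))
    expected_t = 1.0 / sm.hazard[group]
    serum = (sm.serum_mean[group]
             + sm.correlation_sign * sm.serum_survival_slope * (t_surv - expected_t)
             + float(rng.normal(0.0, sm.serum_sd[group])))
    serum = max(serum, 0.0)

    sid = sample_id if sample_id is not None else f"{group}_sample"
    cells = pd.DataFrame({
        "sample_id": sid,
        "cell_id": np.arange(1, n_cells + 1),
        "x": x, "y": y, "area": areas,
        **intensities,
    })
    truth = GroundTruth(
        table=pd.DataFrame({
            "cell_id": np.arange(1, n_cells + 1),
            "true_type": type_arr,
            "cluster_id": cluster_id,
        }),
        applied_effects=effects,
    )
    meta = SampleMetadata(sample_id=sid, group=group, survival_time=t_surv,
                          event=1, serum_ne_dna=serum)
    return SampleResult(cells=cells, ground_truth=truth, metadata=meta)


def simulate_cohort(config: GeneratorConfig, n_per_group: int = 3,
                    seed: int | None = None) -> Cohort:
    """Simulate a balanced two-group cohort (``n_per_group`` NT + IT samples).

    Each sample gets a distinct seed derived from the cohort seed via
    ``numpy.random.SeedSequence.spawn``, so samples are independent and the
    cohort is reproducible from ``(config, n_per_group, seed)`` alone.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if seed is None:
        seed = config.seed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_group)
    samples = []
    i = 0
    for group in GROUPS:
        for j in range(n_per_group):
            sid = f"{group}_{j + 1}"
            samples.append(simulate_sample(config, group,
                                           np.random.default_rng(children[i]),
                                           sample_id=sid))
            i += 1
    return Cohort(samples=samples, config=config)


# ---------------------------------------------------------------------------
# image rendering


def sample_background_levels(cells: pd.DataFrame, markers: Sequence[str],
                             fraction: float) -> dict[str, float]:
    """Background (label-0) channel level per marker.

    Modeled as a fixed fraction of the sample's mean cellular intensity —
    membrane-proximal signal bleeding into the intercellular space — so
    group-level marker shifts are visible outside the cell masks too.
    """
    return {m: fraction * float(cells[m].mean()) if len(cells) else 0.0
            for m in markers}


def render_sample_images(cells: pd.DataFrame, roi_width: float, roi_height: float,
                         markers: Sequence[str] | None = None,
                         background: float | Mapping[str, float] = 0.0,
                         pixel_size: float = 1.0):
    """Render a cell table to a label mask and constant-fill channel images.

    Each cell becomes a disc of ``round(area)`` pixels (the pixels nearest
    its centroid); overlapping pixels go to the lower cell id.  Channel
    images carry the cell's recorded marker intensity on its pixels and the
    ``background`` level on label-0 (intercellular) pixels.

    Returns ``(mask, channels)`` with ``mask`` a 2-D uint16 image
    (0 = intercellular space) and ``channels`` a dict of float32 images.
    """
    if pixel_size != 1.0:
        raise NotImplementedError("only 1 µm/px rendering is supported")
    nrow, ncol = int(round(roi_height)), int(round(roi_width))
    mask = np.zeros((nrow, ncol), dtype=np.uint16)
    if markers is None:
        markers = [c for c in cells.columns if c in PANEL]
    if len(cells):
        if cells["cell_id"].duplicated().any():
            raise ValueError("duplicate cell ids in cell table")
        if ((cells["x"] < 0) | (cells["x"] > roi_width)
                | (cells["y"] < 0) | (cells["y"] > roi_height)).any():
            raise ValueError("cell centroid outside ROI")
        if int(cells["cell_id"].max()) > np.iinfo(np.uint16).max:
            raise ValueError("cell id exceeds 16-bit mask range")

    order = cells.sort_values("cell_id").reset_index(drop=True) if len(cells) else cells
    for row in order.itertuples(index=False):
        n_px = int(round(row.area))
        if n_px <= 0:
            continue
        r = math.ceil(math.sqrt(n_px / math.pi)) + 2
        cx, cy = row.x, row.y
        c0, c1 = max(0, int(cx) - r), min(ncol, int(cx) + r + 1)
        r0, r1 = max(0, int(cy) - r), min(nrow, int(cy) + r + 1)
        rr, cc = np.mgrid[r0:r1, c0:c1]
        d2 = (cc + 0.5 - cx) ** 2 + (rr + 0.5 - cy) ** 2
        flat = np.lexsort((cc.ravel(), rr.ravel(), d2.ravel()))
        rows, cols = rr.ravel()[flat], cc.ravel()[flat]
        take = min(n_px, len(rows))
        sel_r, sel_c = rows[:take], cols[:take]
        free = mask[sel_r, sel_c] == 0
        mask[sel_r[free], sel_c[free]] = row.cell_id

    channels: dict[str, np.ndarray] = {}
    max_label = int(order["cell_id"].max()) if len(order) else 0
    ids = order["cell_id"].to_numpy() if len(order) else np.empty(0, dtype=int)
    for m in markers:
        bg = background[m] if isinstance(background, Mapping) else float(background)
        lut = np.full(max_label + 1, bg, dtype=np.float32)
        if len(order):
            lut[ids] = order[m].to_numpy()
        channels[m] = lut[mask]
    return mask, channels
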