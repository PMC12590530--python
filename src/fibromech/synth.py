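"""Synthetic force-volume, histology and cohort generators with known ground truth.

Every downstream stage of the pipeline (contact-mechanics fitting, elasticity
spectra, collagen quantification, classification) is exercised against data
produced here, where the generating parameters are recorded and can serve as
oracles.  The tissue model is a two-component log-normal mixture of Young's
moduli: a soft "cellular" component (lower elasticity peak, LEP) and a stiff
"collagen" component (higher elasticity peak, HEP) whose weight and position
grow with disease stage.  Force curves follow rigid-cone (Sneddon) contact
mechanics, F = (2/pi) * tan(theta) * E / (1 - nu^2) * delta^2, on top of a
linearly tilted, noisy pre-contact baseline.

Units: piezo displacement z and cantilever deflection in nm, forces in nN,
moduli in kPa, map side in um.  A spring constant in N/m is numerically equal
to nN/nm, which keeps the force arithmetic unit-consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = [
    "CantileverModel",
    "TissueMechanicsModel",
    "NoiseModel",
    "GroupSpec",
    "StudyDesign",
    "ForceCurve",
    "ForceMap",
    "Specimen",
    "Cohort",
    "PolarizedImageSet",
    "SHGStack",
    "STAGES",
    "STAGE_MECHANICS",
    "STAGE_COLLAGEN",
    "sneddon_coefficient",
    "sneddon_force",
    "indentation_at_force",
    "simulate_force_curve",
    "simulate_force_map",
    "simulate_cohort",
    "simulate_polarized_image",
    "render_specimen_image",
    "simulate_shg_stack",
    "paper_design",
    "classification_design",
]

STAGES = (
    "control",
    "inflammation_d3",
    "transition_d14",
    "chronic_d21",
    "pirfenidone_preventive",
    "pirfenidone_therapeutic",
)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CantileverModel:
    """AFM cantilever calibration constants and tip geometry.

    ``spring_constant`` is in N/m (== nN/nm), ``deflection_sensitivity`` in
    nm/V, ``half_open_angle_theta`` in degrees.  ``tip_radius`` (nm) and
    ``resonance_frequency`` (kHz) are carried as metadata only; the contact
    model is an ideal cone.
    """

    spring_constant: float = 0.03
    deflection_sensitivity: float = 50.0
    half_open_angle_theta: float = 20.0
    tip_radius: float = 20.0
    resonance_frequency: float = 15.0

    def __post_init__(self) -> None:
        if self.spring_constant <= 0:
            raise ValueError("spring_constant must be > 0")
        if not 0.0 < self.half_open_angle_theta < 90.0:
            raise ValueError("half_open_angle_theta must be in (0, 90) degrees")
        if self.deflection_sensitivity <= 0:
            raise ValueError("deflection_sensitivity must be > 0")


@dataclass(frozen=True)
class TissueMechanicsModel:
    """Two-component log-normal mixture of Young's moduli for one stage.

    Modes are the back-transformed means on the log10 scale (kPa); log-sds
    are in decades.  ``hep_weight`` is the expected fraction of tissue area
    occupied by the stiff collagen component.
    """

    lep_mode: float = 2.0
    lep_log_sd: float = 0.15
    hep_mode: float = 30.0
    hep_log_sd: float = 0.22
    hep_weight: float = 0.0
    stage_label: str = "control"

    def __post_init__(self) -> None:
        if self.lep_mode <= 0 or self.hep_mode <= 0:
            raise ValueError("mixture modes must be positive")
        if not 0.0 <= self.hep_weight <= 1.0:
            raise ValueError("hep_weight must lie in [0, 1]")
        if self.hep_weight > 0 and self.hep_mode <= self.lep_mode:
            raise ValueError("hep_mode must exceed lep_mode when HEP is present")
        if self.stage_label not in STAGES:
            raise ValueError(f"unknown stage_label {self.stage_label!r}")

    def mean_modulus(self) -> float:
        """Closed-form linear-scale mixture mean (kPa).

        A log10-normal with mode m and log-sd s has linear mean
        m * exp((ln(10) * s)^2 / 2).
        """
        ln10 = math.log(10.0)
        lep = self.lep_mode * math.exp((ln10 * self.lep_log_sd) ** 2 / 2.0)
        hep = self.hep_mode * math.exp((ln10 * self.hep_log_sd) ** 2 / 2.0)
        return (1.0 - self.hep_weight) * lep + self.hep_weight * hep

    def sample_moduli(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` iid moduli (kPa) from the mixture."""
        hep = rng.random(n) < self.hep_weight
        log_e = np.where(
            hep,
            rng.normal(math.log10(self.hep_mode), self.hep_log_sd, n),
            rng.normal(math.log10(self.lep_mode), self.lep_log_sd, n),
        )
        return 10.0 ** log_e

    def sample_field(
        self, grid_points: int, rng: np.random.Generator, smooth_sigma: float = 1.5
    ) -> tuple[np.ndarray, np.ndarray]:
        """Spatially clustered modulus field (kPa) and the HEP mask.

        The HEP component is realized as contiguous patches: a smoothed white
        noise field is thresholded at the (1 - hep_weight) quantile, so the
        expected HEP area fraction equals ``hep_weight`` while pixels cluster
        like collagen bundles in fibrotic histology.
        """
        g = grid_points
        noise_field = gaussian_filter(rng.standard_normal((g, g)), smooth_sigma)
        if self.hep_weight <= 0:
            hep_mask = np.zeros((g, g), dtype=bool)
        elif self.hep_weight >= 1:
            hep_mask = np.ones((g, g), dtype=bool)
        else:
            thr = np.quantile(noise_field, 1.0 - self.hep_weight)
            hep_mask = noise_field > thr
        log_e = rng.normal(math.log10(self.lep_mode), self.lep_log_sd, (g, g))
        if hep_mask.any():
            log_e[hep_mask] = rng.normal(
                math.log10(self.hep_mode), self.hep_log_sd, int(hep_mask.sum())
            )
        return 10.0 ** log_e, hep_mask


@dataclass(frozen=True)
class NoiseModel:
    """Measurement artifacts: white deflection noise, baseline tilt, contact jitter.

    ``deflection_noise_sd`` in nm, ``baseline_tilt`` in nm per um of piezo
    travel, ``contact_point_jitter_sd`` in nm.
    """

    deflection_noise_sd: float = 0.5
    baseline_tilt: float = 0.5
    contact_point_jitter_sd: float = 10.0

    def __post_init__(self) -> None:
        if min(self.deflection_noise_sd, self.baseline_tilt, self.contact_point_jitter_sd) < 0:
            raise ValueError("noise parameters must be non-negative")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0)


@dataclass(frozen=True)
class GroupSpec:
    stage_label: str
    n_specimens: int
    timepoint_days: int
    sex: str = "mixed"

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ValueError("n_specimens must be >= 1")
        if self.stage_label not in STAGES:
            raise ValueError(f"unknown stage_label {self.stage_label!r}")


@dataclass(frozen=True)
class StudyDesign:
    """Cohort layout: groups, maps per specimen, and map geometry."""

    groups: tuple[GroupSpec, ...]
    maps_per_specimen: int = 15
    grid_points: int = 16
    map_side: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.maps_per_specimen < 1:
            raise ValueError("maps_per_specimen must be >= 1")
        if self.grid_points < 2 or self.map_side <= 0:
            raise ValueError("invalid map geometry")


# Stage-dependent mixture defaults.  Published elasticity spectra of fibrotic
# lung are shown on log axes without printed kPa peak positions, so these are
# configuration:
# LEP near 2 kPa (soft parenchyma / cells), HEP rising 10 -> 30 kPa as collagen
# accumulates, HEP weight rising monotonically control -> d3 -> d14 -> d21, and
# the pirfenidone arms reverting toward control (HEP largely absent).
STAGE_MECHANICS: dict[str, TissueMechanicsModel] = {
    "control": TissueMechanicsModel(2.0, 0.15, 10.0, 0.18, 0.03, "control"),
    "inflammation_d3": TissueMechanicsModel(1.8, 0.18, 14.0, 0.20, 0.10, "inflammation_d3"),
    "transition_d14": TissueMechanicsModel(1.8, 0.20, 22.0, 0.20, 0.25, "transition_d14"),
    "chronic_d21": TissueMechanicsModel(1.8, 0.22, 30.0, 0.22, 0.40, "chronic_d21"),
    "pirfenidone_preventive": TissueMechanicsModel(
        1.9, 0.17, 14.0, 0.20, 0.06, "pirfenidone_preventive"
    ),
    "pirfenidone_therapeutic": TissueMechanicsModel(
        1.9, 0.18, 18.0, 0.20, 0.08, "pirfenidone_therapeutic"
    ),
}

# Ground-truth picrosirius collagen fractions of tissue area (type I, type III)
# per stage; they rise with fibrosis progression and revert under treatment.
STAGE_COLLAGEN: dict[str, tuple[float, float]] = {
    "control": (0.02, 0.02),
    "inflammation_d3": (0.04, 0.03),
    "transition_d14": (0.10, 0.05),
    "chronic_d21": (0.16, 0.07),
    "pirfenidone_preventive": (0.04, 0.03),
    "pirfenidone_therapeutic": (0.06, 0.04),
}


@dataclass
class ForceCurve:
    """One approach force-displacement record.

    ``z`` is the strictly monotone piezo displacement ramp (nm); ``deflection``
    the calibrated cantilever deflection (nm) unless ``deflection_v`` holds the
    raw photodiode signal instead.  ``truth`` carries generator ground truth
    (true_E kPa, true contact point) when synthetic.
    """

    z: np.ndarray
    deflection: np.ndarray | None
    cantilever: CantileverModel
    deflection_v: np.ndarray | None = None
    map_index: int = 0
    grid_position: tuple[int, int] = (0, 0)
    truth: dict | None = None

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        signal = self.deflection if self.deflection is not None else self.deflection_v
        if signal is None:
            raise ValueError("curve needs a deflection or deflection_v channel")
        if len(self.z) != len(signal):
            raise ValueError("z and deflection must have equal length")
        if len(self.z) < 50:
            raise ValueError("curve too short (< 50 samples)")
        dz = np.diff(self.z)
        if not (np.all(dz > 0) or np.all(dz < 0)):
            raise ValueError("z must be strictly monotone")

    @property
    def is_calibrated(self) -> bool:
        return self.deflection is not None

    @property
    def force(self) -> np.ndarray:
        """Force channel in nN (spring constant x deflection)."""
        if self.deflection is None:
            raise ValueError("curve is not calibrated; call forcecurves.calibrate")
        return self.cantilever.spring_constant * self.deflection


@dataclass
class ForceMap:
    """Grid of force curves over one map region."""

    curves: list[ForceCurve]
    grid_points: int
    map_side: float
    true_e_grid: np.ndarray | None = None
    hep_mask: np.ndarray | None = None
    cantilever: CantileverModel = field(default_factory=CantileverModel)
    map_index: int = 0

    @property
    def pixel_size(self) -> float:
        """Pixel spacing in um."""
        return self.map_side / self.grid_points

    @property
    def n_curves(self) -> int:
        return len(self.curves)


@dataclass
class Specimen:
    specimen_id: str
    stage_label: str
    timepoint_days: int
    sex: str
    tissue: TissueMechanicsModel
    force_maps: list[ForceMap] | None
    true_maps: list  # list[ElasticityMap] of ground-truth moduli
    col1_fraction: float
    col3_fraction: float
    image_seed: int

    @property
    def label(self) -> str:
        return "control" if self.stage_label == "control" else "bleomycin"


@dataclass
class Cohort:
    design: StudyDesign
    specimens: list[Specimen]

    def by_stage(self, stage: str) -> list[Specimen]:
        return [s for s in self.specimens if s.stage_label == stage]


@dataclass
class PolarizedImageSet:
    """Paired brightfield / crossed-polarizer picrosirius images.

    ``class_map`` is the ground truth: 0 background, 1 plain tissue,
    2 collagen I, 3 collagen III.
    """

    brightfield: np.ndarray
    polarized: np.ndarray
    pixel_size: float = 1.0
    magnification: str = "10x"
    class_map: np.ndarray | None = None


@dataclass
class SHGStack:
    """Repeated raster scans of the same collagen SHG signal."""

    frames: np.ndarray  # (n_frames, h, w)
    signal: np.ndarray | None = None

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


# ---------------------------------------------------------------------------
# Sneddon forward model
# ---------------------------------------------------------------------------

def sneddon_coefficient(theta_deg: float = 20.0, nu: float = 0.5) -> float:
    """Geometry factor (2/pi) tan(theta) / (1 - nu^2) of the conical model."""
    return (2.0 / math.pi) * math.tan(math.radians(theta_deg)) / (1.0 - nu**2)


def sneddon_force(delta_nm: np.ndarray, e_kpa: float, theta_deg: float = 20.0,
                  nu: float = 0.5) -> np.ndarray:
    """Force (nN) at indentation delta (nm) for modulus E (kPa).

    1 kPa * nm^2 = 1e-6 nN, hence the scale factor.
    """
    return sneddon_coefficient(theta_deg, nu) * e_kpa * 1e-6 * np.square(delta_nm)


def indentation_at_force(force_nn: float, e_kpa: float, theta_deg: float = 20.0,
                         nu: float = 0.5) -> float:
    """Closed-form indentation depth (nm) reaching a given force."""
    return math.sqrt(force_nn / (sneddon_coefficient(theta_deg, nu) * e_kpa * 1e-6))


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_force_curve(
    true_e_kpa: float,
    cantilever: CantileverModel | None = None,
    noise: NoiseModel | None = None,
    max_force: float = 1.8,
    seed=0,
    nu: float = 0.5,
    pre_contact_depth: float = 1500.0,
    n_pre: int = 200,
    n_post: int = 600,
    map_index: int = 0,
    grid_position: tuple[int, int] = (0, 0),
) -> ForceCurve:
    """Simulate one approach curve terminating at ``max_force`` (nN).

    The ramp is built around the (jittered) true contact point so that z0 is
    exactly a grid sample; pre-contact deflection is linear tilt plus white
    noise, post-contact deflection solves the coupled cantilever/cone system
    k*d = C*((z - z0) - d)^2 exactly, then noise is added.
    """
    if true_e_kpa <= 0:
        raise ValueError("true_e_kpa must be positive")
    if max_force <= 0:
        raise ValueError("max_force must be positive")
    cantilever = cantilever or CantileverModel()
    noise = noise or NoiseModel()
    rng = _rng(seed)

    k = cantilever.spring_constant  # nN/nm
    c = sneddon_coefficient(cantilever.half_open_angle_theta, nu) * true_e_kpa * 1e-6

    z0 = pre_contact_depth
    if noise.contact_point_jitter_sd > 0:
        z0 += rng.normal(0.0, noise.contact_point_jitter_sd)
    z0 = max(z0, pre_contact_depth * 0.25)

    delta_end = indentation_at_force(max_force, true_e_kpa, cantilever.half_open_angle_theta, nu)
    d_end = max_force / k
    z_end = z0 + (delta_end + d_end) * 1.02  # small overshoot past the force cap

    z_pre = np.linspace(z0 - pre_contact_depth, z0, n_pre + 1)
    z_post = np.linspace(z0, z_end, n_post + 1)[1:]
    z = np.concatenate([z_pre, z_post])

    # contact deflection: positive root of c*d^2 - (2*c*s + k)*d + c*s^2 = 0
    s = np.clip(z - z0, 0.0, None)
    disc = k * (k + 4.0 * c * s)
    d_contact = ((2.0 * c * s + k) - np.sqrt(disc)) / (2.0 * c)

    tilt_slope = noise.baseline_tilt / 1000.0  # nm per nm of travel
    baseline = tilt_slope * z
    deflection = baseline + d_contact
    if noise.deflection_noise_sd > 0:
        deflection = deflection + rng.normal(0.0, noise.deflection_noise_sd, z.size)

    truth = {
        "true_E_kPa": float(true_e_kpa),
        "contact_z0": float(z0),
        "contact_index": n_pre,
        "baseline_slope": tilt_slope,
        "max_force_nN": float(max_force),
        "nu": nu,
    }
    return ForceCurve(
        z=z,
        deflection=deflection,
        cantilever=cantilever,
        map_index=map_index,
        grid_position=grid_position,
        truth=truth,
    )


def simulate_force_map(
    tissue: TissueMechanicsModel,
    cantilever: CantileverModel | None = None,
    noise: NoiseModel | None = None,
    grid_points: int = 16,
    map_side: float = 20.0,
    max_force: float = 1.8,
    seed=0,
    map_index: int = 0,
) -> ForceMap:
    """Simulate a force-volume map: ``grid_points ** 2`` curves with spatially
    clustered ground-truth moduli."""
    cantilever = cantilever or CantileverModel()
    noise = noise or NoiseModel()
    rng = _rng(seed)
    e_grid, hep_mask = tissue.sample_field(grid_points, rng)
    curves = []
    for i in range(grid_points):
        for j in range(grid_points):
            curves.append(
                simulate_force_curve(
                    e_grid[i, j],
                    cantilever,
                    noise,
                    max_force=max_force,
                    seed=rng,
                    map_index=map_index,
                    grid_position=(i, j),
                )
            )
    return ForceMap(
        curves=curves,
        grid_points=grid_points,
        map_side=map_side,
        true_e_grid=e_grid,
        hep_mask=hep_mask,
        cantilever=cantilever,
        map_index=map_index,
    )


def _truth_map(e_grid: np.ndarray, hep_mask: np.ndarray, map_side: float, map_index: int):
    # local import: ElasticityMap lives with the fitting code
    from .forcecurves import ElasticityMap

    g = e_grid.shape[0]
    return ElasticityMap(
        e_kpa=e_grid.copy(),
        qc_mask=np.ones_like(e_grid, dtype=bool),
        reject_codes=np.zeros(e_grid.shape, dtype=int),
        pixel_size=map_side / g,
        specimen_id="",
        map_index=map_index,
        r_squared=np.ones_like(e_grid),
    )


def simulate_cohort(
    design: StudyDesign,
    cantilever: CantileverModel | None = None,
    noise: NoiseModel | None = None,
    include_curves: bool = True,
    collagen_coupling_min_day: int = 14,
) -> Cohort:
    """Simulate a full cohort of specimens, reproducible from ``design.seed``.

    Per specimen the stage mixture is jittered by a log-normal factor on the
    HEP weight; from ``collagen_coupling_min_day`` onward the specimen's
    collagen fractions track that same factor (collagen accumulation drives
    stiffening), while at earlier timepoints collagen is drawn independently
    (inflammation without remodeling).  ``include_curves=False`` skips raw
    force-curve synthesis and stores ground-truth elasticity maps only.
    """
    cantilever = cantilever or CantileverModel()
    noise = noise or NoiseModel()
    rng = np.random.default_rng(design.seed)
    specimens: list[Specimen] = []
    idx = 0
    for group in design.groups:
        base = STAGE_MECHANICS[group.stage_label]
        col1_base, col3_base = STAGE_COLLAGEN[group.stage_label]
        for _ in range(group.n_specimens):
            u = float(np.exp(rng.normal(0.0, 0.15)))
            tissue = replace(
                base,
                hep_weight=float(np.clip(base.hep_weight * u, 0.0, 0.95)),
            )
            if group.timepoint_days >= collagen_coupling_min_day and group.stage_label != "control":
                col_factor = u * float(np.exp(rng.normal(0.0, 0.02)))
            else:
                col_factor = float(np.exp(rng.normal(0.0, 0.15)))
            col1 = float(np.clip(col1_base * col_factor, 0.0, 0.45))
            col3 = float(np.clip(col3_base * col_factor, 0.0, 0.45))
            sex = group.sex if group.sex != "mixed" else ("F" if idx % 2 == 0 else "M")
            force_maps: list[ForceMap] | None = [] if include_curves else None
            true_maps = []
            for m in range(design.maps_per_specimen):
                if include_curves:
                    fmap = simulate_force_map(
                        tissue,
                        cantilever,
                        noise,
                        grid_points=design.grid_points,
                        map_side=design.map_side,
                        seed=rng,
                        map_index=m,
                    )
                    force_maps.append(fmap)
                    true_maps.append(
                        _truth_map(fmap.true_e_grid, fmap.hep_mask, design.map_side, m)
                    )
                else:
                    e_grid, hep_mask = tissue.sample_field(design.grid_points, rng)
                    true_maps.append(_truth_map(e_grid, hep_mask, design.map_side, m))
            spec = Specimen(
                specimen_id=f"S{idx:03d}",
                stage_label=group.stage_label,
                timepoint_days=group.timepoint_days,
                sex=sex,
                tissue=tissue,
                force_maps=force_maps,
                true_maps=true_maps,
                col1_fraction=col1,
                col3_fraction=col3,
                image_seed=int(rng.integers(0, 2**31 - 1)),
            )
            for tm in spec.true_maps:
                tm.specimen_id = spec.specimen_id
            specimens.append(spec)
            idx += 1
    return Cohort(design=design, specimens=specimens)


def paper_design(maps_per_specimen: int = 15, seed: int = 0) -> StudyDesign:
    """The murine study layout: 21 control, 23 bleomycin, 6 per treatment arm."""
    return StudyDesign(
        groups=(
            GroupSpec("control", 5, 3),
            GroupSpec("control", 10, 14),
            GroupSpec("control", 6, 21),
            GroupSpec("inflammation_d3", 5, 3),
            GroupSpec("transition_d14", 11, 14),
            GroupSpec("chronic_d21", 7, 21),
            GroupSpec("pirfenidone_preventive", 6, 14),
            GroupSpec("pirfenidone_therapeutic", 6, 21),
        ),
        maps_per_specimen=maps_per_specimen,
        seed=seed,
    )


def classification_design(
    n_control: int = 16,
    n_bleomycin: int = 17,
    maps_per_specimen: int = 1,
    seed: int = 0,
) -> StudyDesign:
    """Control-vs-bleomycin cohort for the classifier experiments.

    The bleomycin arm mixes disease stages (as in the murine study) so the
    task is learnable but not trivially saturated; one force map per specimen
    is segmented into local sub-grids downstream.
    """
    n3 = n_bleomycin // 3
    n21 = n_bleomycin // 3
    n14 = n_bleomycin - n3 - n21
    return StudyDesign(
        groups=(
            GroupSpec("control", n_control, 21),
            GroupSpec("inflammation_d3", n3, 3),
            GroupSpec("transition_d14", n14, 14),
            GroupSpec("chronic_d21", n21, 21),
        ),
        maps_per_specimen=maps_per_specimen,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Histology / SHG
# ---------------------------------------------------------------------------

_BG_COLOR = np.array([252, 252, 252], dtype=float)
_TISSUE_COLOR = np.array([230, 215, 170], dtype=float)  # pale yellow
_FIBER_BF_COLOR = np.array([180, 40, 45], dtype=float)  # picrosirius red
_DARK_COLOR = np.array([12, 10, 10], dtype=float)
_COL1_POL_COLOR = np.array([230, 90, 20], dtype=float)  # red-orange, hue ~20 deg
_COL3_POL_COLOR = np.array([40, 200, 60], dtype=float)  # green, hue ~128 deg


def _smooth_field(shape, rng, sigma):
    return gaussian_filter(rng.standard_normal(shape), sigma)


def _top_fraction_mask(score: np.ndarray, candidates: np.ndarray, n_pick: int) -> np.ndarray:
    """Exact-count mask of the n_pick highest-scoring candidate pixels."""
    mask = np.zeros(score.shape, dtype=bool)
    if n_pick <= 0:
        return mask
    idx = np.flatnonzero(candidates)
    order = np.argsort(score.ravel()[idx])[::-1]
    mask.ravel()[idx[order[:n_pick]]] = True
    return mask


def simulate_polarized_image(
    col1_fraction: float,
    col3_fraction: float,
    size: int = 256,
    tissue_fraction: float = 0.85,
    seed=0,
    noise_sd: float = 2.0,
    pixel_size: float = 1.0,
) -> PolarizedImageSet:
    """Paired picrosirius-red brightfield / crossed-polarizer images.

    Collagen fractions are *of tissue area* and realized with exact pixel
    counts, so the returned ``class_map`` is an exact oracle.  Brightfield:
    red fibers on pale-yellow tissue, near-white background.  Polarized:
    birefringent collagen I in red-orange, collagen III in green, everything
    else dark.
    """
    for name, f in (("col1_fraction", col1_fraction), ("col3_fraction", col3_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if col1_fraction + col3_fraction > 1.0:
        raise ValueError("collagen fractions exceed tissue area")
    if not 0.0 < tissue_fraction <= 1.0:
        raise ValueError("tissue_fraction must lie in (0, 1]")
    rng = _rng(seed)
    shape = (size, size)

    tissue_score = _smooth_field(shape, rng, size / 16)
    n_tissue = int(round(tissue_fraction * size * size))
    tissue = _top_fraction_mask(tissue_score, np.ones(shape, dtype=bool), n_tissue)

    fiber_score = _smooth_field(shape, rng, 2.0)
    n_col1 = int(round(col1_fraction * n_tissue))
    col1 = _top_fraction_mask(fiber_score, tissue, n_col1)
    fiber_score2 = _smooth_field(shape, rng, 2.0)
    n_col3 = int(round(col3_fraction * n_tissue))
    col3 = _top_fraction_mask(fiber_score2, tissue & ~col1, n_col3)

    class_map = np.zeros(shape, dtype=np.uint8)
    class_map[tissue] = 1
    class_map[col1] = 2
    class_map[col3] = 3

    brightfield = np.empty(shape + (3,), dtype=float)
    brightfield[:] = _BG_COLOR
    brightfield[tissue] = _TISSUE_COLOR
    brightfield[col1 | col3] = _FIBER_BF_COLOR

    polarized = np.empty(shape + (3,), dtype=float)
    polarized[:] = _DARK_COLOR
    polarized[col1] = _COL1_POL_COLOR
    polarized[col3] = _COL3_POL_COLOR

    if noise_sd > 0:
        brightfield += rng.normal(0.0, noise_sd, brightfield.shape)
        polarized += rng.normal(0.0, noise_sd, polarized.shape)
    brightfield = np.clip(brightfield, 0, 255).astype(np.uint8)
    polarized = np.clip(polarized, 0, 255).astype(np.uint8)
    return PolarizedImageSet(
        brightfield=brightfield,
        polarized=polarized,
        pixel_size=pixel_size,
        class_map=class_map,
    )


def render_specimen_image(specimen: Specimen, size: int = 256) -> PolarizedImageSet:
    """Render the picrosirius image pair for a cohort specimen (seeded)."""
    return simulate_polarized_image(
        specimen.col1_fraction,
        specimen.col3_fraction,
        size=size,
        seed=specimen.image_seed,
    )


def simulate_shg_stack(
    n_frames: int,
    signal_image: np.ndarray,
    noise_sd: float,
    seed=0,
) -> SHGStack:
    """Stack of ``n_frames`` independent noisy realizations of one SHG signal."""
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = _rng(seed)
    signal = np.asarray(signal_image, dtype=float)
    frames = np.repeat(signal[None], n_frames, axis=0)
    if noise_sd > 0:
        frames = frames + rng.normal(0.0, noise_sd, frames.shape)
    return SHGStack(frames=frames, signal=signal)
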