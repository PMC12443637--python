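"""Seeded MSI phantom generator.

The phantoms emulate the statistical structure of DESI-MSI lipid imaging
of brain tissue: region-structured geometry (grey matter GM, white
matter WM, tumour T, infiltrated I, necrosis N over background), a lipid
library with region-specific mean abundances including the canonical
brain/glioma marker ions, multiplicative log-normal pixel noise over an
additive background floor, per-spectrum calibration drift, replica
fidelity mixing, per-session batch gains, grade marker effects, and
longitudinal time/treatment effects.

Everything is deterministic given a spec and seed, and each generator
returns ground-truth tables sufficient to compute downstream
expectations without re-reading the generated spectra.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import MSIDataset, SampleMeta, Spectrum
from .errors import SpecError

__all__ = [
    "RegionGeometry",
    "PhantomSpec",
    "CohortSpec",
    "LongitudinalSpec",
    "GroundTruth",
    "default_library",
    "default_regions",
    "generate_section",
    "derive_replica",
    "generate_cohort",
    "generate_longitudinal",
    "MARKER_MZ",
]

REGION_NAMES = ("background", "GM", "WM", "T", "I", "N")

#: the named marker ions (lockmass 885.5498 is listed by its printed label)
MARKER_MZ = {
    "GM": (600.51, 834.53),
    "WM": (844.64, 860.64, 888.62),
    "T": (682.59, 692.45, 716.52, 736.65),
    "N": (680.54,),
    "I": (600.51,),
    "grade_low": (790.55, 834.53),
    "grade_high": (885.5498, 788.55),
    "segmentation": (794.55, 886.60),
}


@dataclass(frozen=True)
class RegionGeometry:
    """A region footprint in physical (mm) coordinates.

    ``kind`` is ``ellipse`` (cx, cy, a, b), ``band`` (axis 'x'|'y', lo,
    hi) or ``annulus`` (cx, cy, r_inner, r_outer). Later regions in a
    spec override earlier ones where they overlap.
    """

    name: str
    kind: str
    params: tuple

    def contains(self, x_mm: np.ndarray, y_mm: np.ndarray) -> np.ndarray:
        if self.kind == "ellipse":
            cx, cy, a, b = self.params
            if a <= 0 or b <= 0:
                raise SpecError(f"ellipse semi-axes must be positive in {self.name}")
            return ((x_mm - cx) / a) ** 2 + ((y_mm - cy) / b) ** 2 <= 1.0
        if self.kind == "band":
            axis, lo, hi = self.params
            if hi <= lo:
                raise SpecError(f"band extent empty in {self.name}")
            v = x_mm if axis == "x" else y_mm
            return (v >= lo) & (v <= hi)
        if self.kind == "annulus":
            cx, cy, r_in, r_out = self.params
            if not 0 <= r_in < r_out:
                raise SpecError(f"annulus radii invalid in {self.name}")
            r = np.hypot(x_mm - cx, y_mm - cy)
            return (r >= r_in) & (r <= r_out)
        raise SpecError(f"unknown geometry kind {self.kind!r}")

    def scaled(self, area_factor: float) -> "RegionGeometry":
        """Rescale the footprint so its area changes by ``area_factor``."""
        if area_factor <= 0:
            raise SpecError("area factor must be positive")
        s = float(np.sqrt(area_factor))
        if self.kind == "ellipse":
            cx, cy, a, b = self.params
            return replace(self, params=(cx, cy, a * s, b * s))
        if self.kind == "band":
            axis, lo, hi = self.params
            mid = (lo + hi) / 2
            half = (hi - lo) / 2 * area_factor  # band area scales linearly with width
            return replace(self, params=(axis, mid - half, mid + half))
        if self.kind == "annulus":
            cx, cy, r_in, r_out = self.params
            return replace(self, params=(cx, cy, r_in * s, r_out * s))
        raise SpecError(f"unknown geometry kind {self.kind!r}")


def default_regions(extent_mm: float = 6.4) -> list[RegionGeometry]:
    """The default three-region phantom: GM disc, WM annulus, tumour ellipse."""
    c = extent_mm / 2
    return [
        RegionGeometry("GM", "ellipse", (c, c, 0.44 * extent_mm, 0.42 * extent_mm)),
        RegionGeometry("WM", "annulus", (c, c, 0.26 * extent_mm, 0.33 * extent_mm)),
        RegionGeometry("T", "ellipse", (0.36 * extent_mm, c, 0.16 * extent_mm, 0.13 * extent_mm)),
    ]


def default_library(
    n_species: int = 600,
    mz_range: tuple[float, float] = (600.0, 900.0),
    seed: int = 7,
    n_discriminants: int = 10,
) -> pd.DataFrame:
    """The default lipid library: 600 species over m/z 600–900.

    Columns: ``mz``, one mean-abundance column per region name, ``cv``
    (within-region coefficient of variation placeholder, informational),
    and ``role`` ∈ {marker, discriminant, helper, null}. Null species
    share one mean across all tissue regions; the ten GM-vs-T
    discriminants carry an 8-fold GM excess; marker ions carry the
    region contrasts the figures rely on.
    """
    rng = np.random.default_rng(seed)
    named = {
        # mz: (GM, WM, T, I, N, role)
        600.51: (4.0, 0.8, 0.8, 5.0, 0.5, "marker"),
        680.54: (0.5, 0.5, 0.5, 0.5, 5.0, "marker"),
        682.59: (0.5, 0.5, 5.0, 0.5, 0.5, "marker"),
        692.45: (1.0, 1.0, 8.0, 1.0, 1.0, "marker"),
        716.52: (0.5, 0.5, 4.0, 0.5, 0.5, "marker"),
        736.65: (0.5, 0.5, 5.0, 0.5, 0.5, "marker"),
        788.55: (1.0, 1.0, 1.0, 1.0, 1.0, "marker"),
        790.55: (1.5, 1.5, 1.5, 1.5, 1.5, "marker"),
        794.55: (6.0, 6.0, 6.0, 6.0, 6.0, "helper"),
        834.53: (6.0, 1.0, 1.0, 2.0, 0.5, "marker"),
        844.64: (0.5, 4.0, 0.5, 0.5, 0.5, "marker"),
        860.64: (0.5, 4.0, 0.5, 0.5, 0.5, "marker"),
        885.5498: (5.0, 5.0, 5.0, 5.0, 5.0, "marker"),
        886.60: (6.0, 6.0, 6.0, 6.0, 6.0, "helper"),
        888.62: (1.0, 8.0, 2.0, 1.0, 1.0, "marker"),
    }
    n_random = n_species - len(named) - n_discriminants
    if n_random < 0:
        raise SpecError("library too small for the named species")
    lo, hi = mz_range
    taken = np.array(sorted(named))
    # one species per 0.5-m/z slot, clear of the named ions, so that each
    # species maps to its own feature even on a coarse analysis binning
    # (the cohort-level representations emulate one peak-picked feature
    # per lipid, as vendor peak lists do)
    slot = 0.5
    centres = np.arange(lo + slot / 2, hi, slot)
    free = centres[np.abs(centres[:, None] - taken[None, :]).min(axis=1) > 0.6]
    if n_discriminants > free.size:
        raise SpecError("library too dense for collision-free placement")
    order = rng.permutation(free.size)
    disc_slots = free[order[:n_discriminants]]
    null_pool = free[order[n_discriminants:]]
    # null species may share a slot with each other (both are contrast-free);
    # species carrying a region contrast always get an exclusive slot
    reps = int(np.ceil(n_random / null_pool.size))
    null_slots = np.tile(null_pool, reps)[:n_random]
    slot_counts = pd.Series(null_slots).value_counts()
    null_shared = slot_counts.loc[null_slots].to_numpy() > 1
    disc_mz = disc_slots + rng.uniform(-0.15, 0.15, size=n_discriminants)
    random_mz = null_slots + rng.uniform(-0.15, 0.15, size=n_random)

    rows = []
    for mz, (gm, wm, t, i_, n_, role) in named.items():
        rows.append(dict(mz=mz, GM=gm, WM=wm, T=t, I=i_, N=n_, role=role, shared=False))
    for mz in disc_mz:
        base = float(rng.uniform(2.0, 4.0))
        rows.append(
            dict(mz=mz, GM=base, WM=base / 2, T=base / 8.0, I=base, N=base / 8.0,
                 role="discriminant", shared=False)
        )
    for mz, shared in zip(random_mz, null_shared):
        base = float(np.exp(rng.normal(-0.5, 0.8)))
        rows.append(dict(mz=mz, GM=base, WM=base, T=base, I=base, N=base,
                         role="null", shared=bool(shared)))
    lib = pd.DataFrame(rows).sort_values("mz").reset_index(drop=True)
    lib["background"] = 0.0
    lib["cv"] = 0.4
    return lib


@dataclass
class PhantomSpec:
    """Everything needed to render one synthetic MSI sample."""

    grid: tuple[int, int] = (64, 64)  # (nx, ny)
    pixel_size: float = 100.0  # µm
    regions: list[RegionGeometry] | None = None  # default: three-region layout scaled to the grid
    library: pd.DataFrame | None = None
    noise_sigma: float = 0.4  # log-normal sigma of pixel×species noise
    background_floor: float = 0.02  # scale of the additive background noise
    resolving_power: float = 20000.0
    drift_range: float = 0.0  # per-spectrum calibration drift, uniform ±drift
    render: str = "centroid"  # or "profile" (Gaussian peak shapes)
    seed: int = 0

    def resolved_library(self) -> pd.DataFrame:
        return self.library if self.library is not None else default_library()

    def resolved_regions(self) -> list[RegionGeometry]:
        if self.regions is not None:
            return self.regions
        return default_regions(min(self.extent_mm))

    @property
    def extent_mm(self) -> tuple[float, float]:
        return (
            self.grid[0] * self.pixel_size / 1000.0,
            self.grid[1] * self.pixel_size / 1000.0,
        )


@dataclass
class GroundTruth:
    """Ground truth accompanying a generated dataset."""

    mask: np.ndarray  # (ny, nx) bool, tissue
    labels: np.ndarray  # (ny, nx) int region index, -1 background
    region_names: dict[int, str]
    library: pd.DataFrame  # region means actually used (after any effects)
    abundance: np.ndarray  # (n_pixels, n_species) true abundances
    coords: np.ndarray  # (n_pixels, 2)

    def region_pixels(self, name: str) -> np.ndarray:
        idx = [k for k, v in self.region_names.items() if v == name]
        if not idx:
            raise SpecError(f"no region named {name!r}")
        flat = self.labels[self.coords[:, 1], self.coords[:, 0]]
        return np.flatnonzero(np.isin(flat, idx))


def truth_region_labels(truth: "GroundTruth", pixel_size: float):
    """Ground-truth region assignment as a :class:`~replicamap.regions.RegionLabels`.

    Lets downstream region statistics (areas, tumour abundances) run on
    the generator's true labels instead of a clustering.
    """
    from .regions import RegionLabels

    return RegionLabels(
        labels=truth.labels[truth.coords[:, 1], truth.coords[:, 0]],
        coords=truth.coords.copy(),
        pixel_size=pixel_size,
        region_names=dict(truth.region_names),
    )


def _region_label_grid(spec: PhantomSpec) -> tuple[np.ndarray, dict[int, str]]:
    nx, ny = spec.grid
    if nx < 1 or ny < 1:
        raise SpecError("grid must be at least 1×1")
    xs = (np.arange(nx) + 0.5) * spec.pixel_size / 1000.0
    ys = (np.arange(ny) + 0.5) * spec.pixel_size / 1000.0
    X, Y = np.meshgrid(xs, ys)
    ex, ey = spec.extent_mm
    labels = np.full((ny, nx), -1, dtype=int)
    names: dict[int, str] = {}
    for i, region in enumerate(spec.resolved_regions()):
        if region.name not in REGION_NAMES:
            raise SpecError(f"unknown region name {region.name!r}")
        inside = region.contains(X, Y)
        if not inside.any():
            raise SpecError(f"region {region.name} lies outside the grid")
        labels[inside] = i
        names[i] = region.name
    return labels, names


def _render_spectrum(
    mz: np.ndarray,
    abundance: np.ndarray,
    spec: PhantomSpec,
    drift: float,
) -> Spectrum:
    if spec.render == "centroid":
        return Spectrum(mz + drift, abundance)
    # Gaussian profile: ±2 FWHM at FWHM/4 sampling, area-preserving
    fwhm = mz / spec.resolving_power
    sigma = fwhm / 2.3548200450309493
    offsets = np.linspace(-2, 2, 17)
    grid = (mz[:, None] + offsets[None, :] * fwhm[:, None]).ravel()
    weights = np.exp(-0.5 * (offsets * fwhm[:, None] / sigma[:, None]) ** 2)
    weights /= weights.sum(axis=1, keepdims=True)
    inten = (abundance[:, None] * weights).ravel()
    order = np.argsort(grid, kind="stable")
    grid, inten = grid[order], inten[order]
    keep = np.concatenate([[True], np.diff(grid) > 0])
    return Spectrum(grid[keep] + drift, inten[keep])


def generate_section(
    spec: PhantomSpec, meta: SampleMeta | None = None
) -> tuple[MSIDataset, GroundTruth]:
    """Render one phantom section.

    Per tissue pixel, the true abundance of each species is its region
    mean times a log-normal factor exp(N(0, σ)); every pixel (tissue and
    background) additionally receives an exponential additive floor with
    scale ``background_floor``. Optional per-spectrum calibration drift
    is uniform in ±``drift_range``. Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    library = spec.resolved_library()
    labels, names = _region_label_grid(spec)
    nx, ny = spec.grid
    ys, xs = np.mgrid[0:ny, 0:nx]
    coords = np.column_stack([xs.ravel(), ys.ravel()])
    flat_labels = labels[coords[:, 1], coords[:, 0]]

    mz = library["mz"].to_numpy()
    n_pix, n_sp = coords.shape[0], mz.size
    means = np.zeros((n_pix, n_sp))
    for i, name in names.items():
        means[flat_labels == i] = library[name].to_numpy()

    noise = np.exp(rng.normal(0.0, spec.noise_sigma, size=(n_pix, n_sp)))
    abundance = means * noise
    floor = rng.exponential(spec.background_floor, size=(n_pix, n_sp))
    rendered = abundance + floor
    drifts = (
        rng.uniform(-spec.drift_range, spec.drift_range, size=n_pix)
        if spec.drift_range > 0
        else np.zeros(n_pix)
    )
    spectra = [
        _render_spectrum(mz, rendered[p], spec, drifts[p]) for p in range(n_pix)
    ]
    if meta is None:
        meta = SampleMeta(sample_id=f"phantom-{spec.seed}", kind="section")
    dataset = MSIDataset(coords, spectra, spec.pixel_size, meta)
    truth = GroundTruth(
        mask=labels >= 0,
        labels=labels,
        region_names=names,
        library=library,
        abundance=abundance,
        coords=coords,
    )
    return dataset, truth


def derive_replica(
    section: MSIDataset,
    truth: GroundTruth,
    spec: PhantomSpec,
    fidelity: float = 0.9,
    misregistration: tuple[int, int] = (0, 0),
    gain: float = 1.0,
    seed: int = 1,
    meta: SampleMeta | None = None,
) -> MSIDataset:
    """Derive a molecular replica from a section.

    Replica abundance = gain × (fidelity × section abundance +
    (1 − fidelity) × independent redraw around the same region means),
    then an integer-pixel spatial shift (vacated pixels fall back to
    background). fidelity 1, gain 1, shift (0, 0) reproduces the section
    spectra exactly.
    """
    if not 0.0 <= fidelity <= 1.0:
        raise SpecError("fidelity must lie in [0, 1]")
    if meta is None:
        meta = SampleMeta(
            sample_id=section.meta.sample_id + "-r",
            kind="replica",
            patient_id=section.meta.patient_id,
            batch_id=section.meta.batch_id,
            grade=section.meta.grade,
            timepoint=section.meta.timepoint,
            treatment=section.meta.treatment,
        )
    if fidelity == 1.0 and gain == 1.0 and misregistration == (0, 0):
        return MSIDataset(
            section.coords.copy(), list(section.spectra), section.pixel_size, meta
        )
    rng = np.random.default_rng(seed)
    library = truth.library
    mz = library["mz"].to_numpy()
    coords = truth.coords
    flat_labels = truth.labels[coords[:, 1], coords[:, 0]]
    n_pix, n_sp = truth.abundance.shape
    means = np.zeros((n_pix, n_sp))
    for i, name in truth.region_names.items():
        means[flat_labels == i] = library[name].to_numpy()
    redraw = means * np.exp(rng.normal(0.0, spec.noise_sigma, size=(n_pix, n_sp)))
    mixed = gain * (fidelity * truth.abundance + (1.0 - fidelity) * redraw)

    dx, dy = misregistration
    if dx or dy:
        ny, nx = truth.labels.shape
        grid = np.zeros((ny, nx, n_sp))
        grid[coords[:, 1], coords[:, 0]] = mixed
        shifted = np.zeros_like(grid)
        src_y = np.clip(np.arange(ny) - dy, 0, ny - 1)
        src_x = np.clip(np.arange(nx) - dx, 0, nx - 1)
        valid_y = (np.arange(ny) - dy >= 0) & (np.arange(ny) - dy < ny)
        valid_x = (np.arange(nx) - dx >= 0) & (np.arange(nx) - dx < nx)
        shifted = grid[src_y][:, src_x]
        shifted[~valid_y, :, :] = 0.0
        shifted[:, ~valid_x, :] = 0.0
        mixed = shifted[coords[:, 1], coords[:, 0]]

    floor = rng.exponential(spec.background_floor, size=(n_pix, n_sp))
    rendered = mixed + floor
    spectra = [Spectrum(mz, rendered[p]) for p in range(n_pix)]
    return MSIDataset(coords.copy(), spectra, section.pixel_size, meta)


@dataclass
class CohortSpec:
    """A grading cohort: sections and replicas from ``n_patients`` biopsies.

    Grade marker effects multiply the tissue means of the named markers
    in patients of the matching grade. Batch gains are per-session,
    per-species multiplicative log-normal vectors (a scalar session gain
    would vanish under TIC normalization). Patient-to-patient profile
    variation is a per-patient log-normal multiplier per species.
    """

    n_patients: int = 23
    grid: tuple[int, int] = (16, 16)
    pixel_size: float = 150.0
    library: pd.DataFrame | None = None
    # ×6 keeps each marker's grade shift ≈ 4.5 patient-s.d. (log scale), so
    # the planted separation dominates inter-patient profile variability
    grade_effects: dict = field(
        default_factory=lambda: {
            "low": {790.55: 6.0, 834.53: 6.0},
            "high": {885.5498: 6.0, 788.55: 6.0},
        }
    )
    n_sessions: int = 4
    batch_sigma: float = 0.15
    patient_sigma: float = 0.4
    replica_fidelity: float = 0.9
    noise_sigma: float = 0.4
    background_floor: float = 0.02
    seed: int = 0

    def resolved_library(self) -> pd.DataFrame:
        return self.library if self.library is not None else default_library()


def _cohort_regions(extent_mm: float) -> list[RegionGeometry]:
    c = extent_mm / 2
    return [RegionGeometry("T", "ellipse", (c, c, 0.40 * extent_mm, 0.34 * extent_mm))]


def generate_cohort(
    spec: CohortSpec,
) -> tuple[list[tuple[MSIDataset, GroundTruth]], list[tuple[MSIDataset, GroundTruth]], pd.DataFrame]:
    """Generate the grading cohort: one section + one replica per patient.

    Grades alternate (ceil(n/2) high), sessions are assigned round-robin
    (a patient's section and replica share a session). Returns
    (sections, replicas, metadata table); ground truths carry each
    patient's effective library.
    """
    if spec.n_patients < 2:
        raise SpecError("need at least two patients")
    rng = np.random.default_rng(spec.seed)
    base_library = spec.resolved_library()
    mz = base_library["mz"].to_numpy()
    extent = spec.grid[0] * spec.pixel_size / 1000.0
    batch_gains = {
        f"S{b}": np.exp(rng.normal(0.0, spec.batch_sigma, size=mz.size))
        for b in range(spec.n_sessions)
    }
    # session assignment is shuffled so grades mix within every session
    # (a session carrying a single grade would confound batch with grade)
    session_of = rng.permutation(
        np.arange(spec.n_patients) % spec.n_sessions
    )
    sections, replicas, meta_rows = [], [], []
    for p in range(spec.n_patients):
        grade = "high" if p % 2 == 0 else "low"
        batch = f"S{session_of[p]}"
        lib = base_library.copy()
        patient_factor = np.exp(rng.normal(0.0, spec.patient_sigma, size=mz.size))
        factor = patient_factor * batch_gains[batch]
        for marker_mz, mult in spec.grade_effects.get(grade, {}).items():
            j = int(np.argmin(np.abs(mz - marker_mz)))
            if abs(mz[j] - marker_mz) > 0.05:
                raise SpecError(f"grade marker m/z {marker_mz} absent from library")
            factor[j] *= mult
        for col in ("GM", "WM", "T", "I", "N"):
            lib[col] = base_library[col].to_numpy() * factor

        sec_meta = SampleMeta(
            sample_id=f"HG{p:02d}-s",
            kind="section",
            patient_id=f"P{p:02d}",
            batch_id=batch,
            grade=grade,
        )
        phantom = PhantomSpec(
            grid=spec.grid,
            pixel_size=spec.pixel_size,
            regions=_cohort_regions(extent),
            library=lib,
            noise_sigma=spec.noise_sigma,
            background_floor=spec.background_floor,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        section, truth = generate_section(phantom, meta=sec_meta)
        rep_meta = SampleMeta(
            sample_id=f"HG{p:02d}-r",
            kind="replica",
            patient_id=f"P{p:02d}",
            batch_id=batch,
            grade=grade,
        )
        replica = derive_replica(
            section,
            truth,
            phantom,
            fidelity=spec.replica_fidelity,
            seed=int(rng.integers(0, 2**31 - 1)),
            meta=rep_meta,
        )
        sections.append((section, truth))
        replicas.append((replica, truth))
        meta_rows.append(sec_meta.to_row())
        meta_rows.append(rep_meta.to_row())
    metadata = pd.DataFrame(meta_rows)
    return sections, replicas, metadata


@dataclass
class LongitudinalSpec:
    """The longitudinal design: brains × {D0, D5} × {T0, T1}.

    Day-5 geometry factors rescale region areas (grey matter grows,
    white matter shrinks; the tumour shrinks under treatment, grows
    slightly without). The treatment effect table multiplies tumour
    means of selected species in treated day-5 samples (692.45 → 0 by
    default); time-effect species are shifted identically in both arms.
    """

    n_brains: int = 3
    grid: tuple[int, int] = (48, 48)
    pixel_size: float = 100.0
    library: pd.DataFrame | None = None
    gm_growth: float = 1.15
    wm_shrink: float = 0.8
    tumour_untreated: float = 1.1
    tumour_treated: float = 0.5
    treatment_effects: dict | None = None  # mz -> multiplier in treated D5 tumour
    n_time_increase: int = 8
    n_time_decrease: int = 19
    time_increase_factor: float = 8.0
    time_decrease_factor: float = 0.1
    brain_sigma: float = 0.05
    noise_sigma: float = 0.3
    background_floor: float = 0.02
    seed: int = 0

    def resolved_library(self) -> pd.DataFrame:
        return self.library if self.library is not None else default_library()


def _default_treatment_effects(library: pd.DataFrame, rng) -> dict[float, float]:
    """692.45 zeroed, plus 7 more decreasing and 3 increasing null species.

    Effects are planted on well-detected species (tumour mean ≥ 1):
    the response of a barely detectable lipid is not a usable positive
    control for the ΔT screen.
    """
    mz = library["mz"].to_numpy()
    nulls = library.index[
        (library["role"] == "null") & (library["T"] >= 1.0) & ~library["shared"]
    ].to_numpy()
    chosen = rng.choice(nulls, size=10, replace=False)
    effects: dict[float, float] = {692.45: 0.0}
    for idx in chosen[:7]:
        effects[float(mz[idx])] = 0.25
    for idx in chosen[7:]:
        effects[float(mz[idx])] = 4.0
    return effects


def generate_longitudinal(
    spec: LongitudinalSpec,
) -> tuple[dict[tuple[str, str, str], tuple[MSIDataset, GroundTruth]], dict]:
    """Generate the full longitudinal dataset grid.

    Returns (datasets keyed by (brain_id, timepoint, arm), effect tables).
    Effect tables: ``treatment_effects`` (mz → treated-D5 multiplier),
    ``time_effects`` (mz → D5 multiplier applied in both arms).
    """
    rng = np.random.default_rng(spec.seed)
    base_library = spec.resolved_library()
    mz = base_library["mz"].to_numpy()
    treatment_effects = (
        dict(spec.treatment_effects)
        if spec.treatment_effects is not None
        else _default_treatment_effects(base_library, rng)
    )
    # time-effect species: exclusive-slot, detectable nulls (a 10-fold drop
    # of a species near the background floor is not recoverable by design)
    null_idx = base_library.index[
        (base_library["role"] == "null")
        & (base_library["T"] >= 0.5)
        & ~base_library["shared"]
    ].to_numpy()
    treated_idx = {int(np.argmin(np.abs(mz - m))) for m in treatment_effects}
    free_nulls = np.array([i for i in null_idx if i not in treated_idx])
    picks = rng.choice(
        free_nulls, size=spec.n_time_increase + spec.n_time_decrease, replace=False
    )
    time_effects: dict[float, float] = {}
    for idx in picks[: spec.n_time_increase]:
        time_effects[float(mz[idx])] = spec.time_increase_factor
    for idx in picks[spec.n_time_increase :]:
        time_effects[float(mz[idx])] = spec.time_decrease_factor

    extent = spec.grid[0] * spec.pixel_size / 1000.0
    datasets: dict[tuple[str, str, str], tuple[MSIDataset, GroundTruth]] = {}
    for b in range(spec.n_brains):
        brain = f"B{b + 1}"
        brain_factor = np.exp(rng.normal(0.0, spec.brain_sigma, size=mz.size))
        lib_d0 = base_library.copy()
        for col in ("GM", "WM", "T", "I", "N"):
            lib_d0[col] = base_library[col].to_numpy() * brain_factor
        regions_d0 = default_regions(extent)
        for arm in ("T0", "T1"):
            for timepoint in ("D0", "D5"):
                lib = lib_d0.copy()
                regions = regions_d0
                if timepoint == "D5":
                    time_factor = np.ones(mz.size)
                    for m, f in time_effects.items():
                        time_factor[int(np.argmin(np.abs(mz - m)))] = f
                    for col in ("GM", "WM", "T", "I", "N"):
                        lib[col] = lib[col].to_numpy() * time_factor
                    if arm == "T1":
                        treat_factor = np.ones(mz.size)
                        for m, f in treatment_effects.items():
                            treat_factor[int(np.argmin(np.abs(mz - m)))] = f
                        lib["T"] = lib["T"].to_numpy() * treat_factor
                    tum = spec.tumour_treated if arm == "T1" else spec.tumour_untreated
                    scale = {"GM": spec.gm_growth, "WM": spec.wm_shrink, "T": tum}
                    regions = [r.scaled(scale.get(r.name, 1.0)) for r in regions_d0]
                meta = SampleMeta(
                    sample_id=f"{brain}-{timepoint}{arm}",
                    kind="replica",
                    patient_id=brain,
                    batch_id=f"{brain}-{timepoint}",
                    timepoint=timepoint,
                    treatment=arm,
                )
                phantom = PhantomSpec(
                    grid=spec.grid,
                    pixel_size=spec.pixel_size,
                    regions=regions,
                    library=lib,
                    noise_sigma=spec.noise_sigma,
                    background_floor=spec.background_floor,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                datasets[(brain, timepoint, arm)] = generate_section(phantom, meta=meta)
    tables = {
        "treatment_effects": treatment_effects,
        "time_effects": time_effects,
    }
    return datasets, tables
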