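"""Synthetic cohorts of modulated gray-matter volume images.

Real voxel-based-morphometry studies start from spatially normalized,
Jacobian-modulated gray-matter segments whose voxel sum approximates the
subject's total gray matter volume (GMV, in ml).  This module generates
seeded stand-in cohorts with the statistical structure such an analysis
assumes: a demographic table (sex, age, total intracranial volume), an
ellipsoidal brain mask partitioned into atlas regions, and per-subject
images in which each region's volume follows a power law in TIV with an
optional multiplicative sex effect,

    V_i = a_i * (TIV / TIV_ref)**beta_i * (1 + s_i * 1[female]),

spread uniformly over the region's voxels plus truncated-at-zero noise.
Heterogeneous exponents ``beta_i`` are what leaves decodable TIV
information in per-image z-score-normalized data; with all ``beta_i = 1``
and no noise, normalization makes same-sex images identical.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml
from scipy import stats

__all__ = [
    "SubjectRecord",
    "CohortProfile",
    "ROIAtlas",
    "EffectSpec",
    "GMVImage",
    "Cohort",
    "SHIP_PROFILE",
    "HCP_PROFILE",
    "sample_demographics",
    "build_atlas",
    "synthesize_image",
    "simulate_cohort",
    "write_cohort",
    "read_cohort",
    "default_effects",
    "load_profile",
    "save_profile",
]

#: Full-resolution grid of the reference (MNI-space) images and its voxel size.
FULL_GRID = (113, 137, 113)
FULL_VOXEL_MM = 1.5
#: Desk-scale default grid, same aspect ratio as the full grid.
DESK_GRID = (32, 38, 32)


@dataclass(frozen=True)
class SubjectRecord:
    """Demographic / volumetric metadata for one scan."""

    subject_id: str
    sex: str  # "male" | "female"
    age_years: float
    tiv_ml: float
    cohort_label: str


@dataclass(frozen=True)
class TruncNormLaw:
    """Truncated normal with explicit support bounds."""

    mean: float
    sd: float
    lo: float
    hi: float

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        a = (self.lo - self.mean) / self.sd
        b = (self.hi - self.mean) / self.sd
        return stats.truncnorm.rvs(a, b, loc=self.mean, scale=self.sd,
                                   size=n, random_state=rng)


@dataclass(frozen=True)
class CohortProfile:
    """Marginal laws of a cohort: size, sex ratio, age and per-sex TIV."""

    name: str
    n: int
    male_fraction: float
    age_law: TruncNormLaw
    tiv_law_male: TruncNormLaw
    tiv_law_female: TruncNormLaw
    gmv_fraction: float  # mean GMV / mean TIV of the emulated cohort

    def __post_init__(self) -> None:
        if not 0.0 <= self.male_fraction <= 1.0:
            raise ValueError("male_fraction must lie in [0, 1]")
        for law in (self.age_law, self.tiv_law_male, self.tiv_law_female):
            if law.lo >= law.hi:
                raise ValueError(
                    f"invalid profile bounds: min {law.lo} >= max {law.hi}")


# Two population profiles: a large adult cohort spanning ages 21-90 and a
# smaller young-adult cohort (ages 22-36).  TIV means/ranges and the GMV/TIV
# fractions follow the published cohort summaries; the TIV and age spreads
# are free parameters chosen to give realistic overlap between sexes.
SHIP_PROFILE = CohortProfile(
    name="ship",
    n=3298,
    male_fraction=0.487,
    age_law=TruncNormLaw(53.0, 16.0, 21.0, 90.0),
    tiv_law_male=TruncNormLaw(1609.0, 130.0, 946.0, 2209.0),
    tiv_law_female=TruncNormLaw(1406.0, 125.0, 946.0, 2209.0),
    gmv_fraction=625.8 / 1505.0,
)

HCP_PROFILE = CohortProfile(
    name="hcp",
    n=399,
    male_fraction=0.464,
    age_law=TruncNormLaw(29.0, 3.5, 22.0, 36.0),
    tiv_law_male=TruncNormLaw(1584.0, 120.0, 1028.0, 1880.0),
    tiv_law_female=TruncNormLaw(1367.0, 115.0, 1028.0, 1880.0),
    gmv_fraction=719.1 / 1468.0,
)


@dataclass
class ROIAtlas:
    """Integer-labelled parcellation of an ellipsoidal brain mask.

    Label 0 marks voxels outside the mask; labels 1..n_regions partition the
    mask into contiguous nearest-seed (Voronoi) regions.
    """

    label_grid: np.ndarray  # int, shape grid_dims
    label_table: dict[int, str]
    voxel_size_mm: float

    @property
    def grid_dims(self) -> tuple[int, int, int]:
        return tuple(self.label_grid.shape)

    @property
    def mask(self) -> np.ndarray:
        return self.label_grid > 0

    @property
    def n_regions(self) -> int:
        return len(self.label_table)

    def region_voxel_counts(self) -> dict[int, int]:
        labels, counts = np.unique(self.label_grid[self.label_grid > 0],
                                   return_counts=True)
        return dict(zip(labels.tolist(), counts.tolist()))

    def region_mask(self, label: int) -> np.ndarray:
        if label not in self.label_table:
            raise KeyError(f"unknown region label {label}")
        return self.label_grid == label


@dataclass
class EffectSpec:
    """Regional volume laws: base volumes, TIV exponents, sex effects, noise.

    ``base_volume_ml[i]`` is region i's expected volume at ``tiv_ref_ml``;
    ``tiv_exponent[i]`` its power-law exponent beta_i; ``sex_effect[i]`` a
    multiplicative effect applied for female subjects; ``noise_sd_ml`` the
    i.i.d. per-voxel noise standard deviation (truncated at zero after
    addition).
    """

    base_volume_ml: np.ndarray
    tiv_exponent: np.ndarray
    sex_effect: np.ndarray
    noise_sd_ml: float
    tiv_ref_ml: float
    #: sd of the per-subject global lognormal GMV scale (individual variation
    #: in the GMV/TIV ratio); multiplicative on the whole image, hence removed
    #: by per-image z-score normalization.
    subject_sd: float = 0.0
    #: sd of per-region, per-subject lognormal volume variation — individual
    #: anatomical variability of regional volumes beyond the TIV power law.
    region_sd: float = 0.0

    def __post_init__(self) -> None:
        self.base_volume_ml = np.asarray(self.base_volume_ml, dtype=float)
        self.tiv_exponent = np.asarray(self.tiv_exponent, dtype=float)
        self.sex_effect = np.asarray(self.sex_effect, dtype=float)
        if np.any(self.base_volume_ml <= 0):
            raise ValueError("base volumes must be positive")
        if np.any(self.tiv_exponent <= 0):
            raise ValueError("TIV exponents must be positive")
        if np.any(self.sex_effect <= -1.0):
            raise ValueError("sex effect <= -1 gives non-positive volume")

    @property
    def n_regions(self) -> int:
        return len(self.base_volume_ml)


def default_effects(
    atlas: ROIAtlas,
    profile: CohortProfile,
    seed: int,
    *,
    beta_range: tuple[float, float] = (0.7, 1.2),
    density_range: tuple[float, float] = (0.6, 1.4),
    sex_effect_sd: float = 0.04,
    noise_rel: float = 0.2,
    subject_sd: float = 0.1,
    region_sd: float = 0.05,
) -> EffectSpec:
    """Draw a seeded default :class:`EffectSpec` for an atlas and profile.

    Regional densities (per-voxel gray-matter content) and power-law
    exponents are drawn uniformly, so normalized images carry residual TIV
    information; small zero-mean multiplicative sex effects distributed over
    all regions emulate the broad, modest regional sex differences the
    analysis targets.  Base volumes are scaled so the expected total GMV at
    the reference TIV equals ``profile.gmv_fraction * tiv_ref``.
    """
    rng = np.random.default_rng(seed)
    counts = atlas.region_voxel_counts()
    n_vox = np.array([counts[i + 1] for i in range(atlas.n_regions)], float)
    density = rng.uniform(*density_range, size=atlas.n_regions)
    tiv_ref = (profile.tiv_law_male.mean + profile.tiv_law_female.mean) / 2.0
    gmv_ref = profile.gmv_fraction * tiv_ref
    base = n_vox * density
    base *= gmv_ref / base.sum()
    beta = rng.uniform(*beta_range, size=atlas.n_regions)
    s = rng.normal(0.0, sex_effect_sd, size=atlas.n_regions)
    s = np.clip(s, -0.5, 0.5)
    mean_voxel = gmv_ref / n_vox.sum()
    return EffectSpec(
        base_volume_ml=base,
        tiv_exponent=beta,
        sex_effect=s,
        noise_sd_ml=noise_rel * mean_voxel,
        tiv_ref_ml=tiv_ref,
        subject_sd=subject_sd,
        region_sd=region_sd,
    )


@dataclass
class GMVImage:
    """One subject's modulated gray-matter image; voxel sum ~ GMV in ml."""

    values: np.ndarray
    subject_id: str

    @property
    def voxel_sum(self) -> float:
        return float(self.values.sum())


@dataclass
class Cohort:
    """A simulated cohort: records + image stack + atlas + generating spec."""

    records: list[SubjectRecord]
    images: np.ndarray  # float32, shape (n,) + grid_dims
    atlas: ROIAtlas
    effects: EffectSpec
    gmv_ml: np.ndarray  # realized voxel sums

    @property
    def n(self) -> int:
        return len(self.records)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame([dataclasses.asdict(r) for r in self.records])
        df["gmv_ml"] = self.gmv_ml
        return df

    @property
    def labels(self) -> np.ndarray:
        """Femaleness labels: 1 for female, 0 for male."""
        return np.array([1 if r.sex == "female" else 0 for r in self.records])


def sample_demographics(
    profile: CohortProfile,
    seed: int,
    *,
    exact_counts: bool = True,
) -> list[SubjectRecord]:
    """Sample ``profile.n`` subject records under a seeded generator.

    Sex counts are exact (``round(n * male_fraction)`` males) by default so
    downstream matching is stable; pass ``exact_counts=False`` for a
    binomial draw.
    """
    if profile.n < 2:
        raise ValueError("need n >= 2")
    rng = np.random.default_rng(seed)
    n = profile.n
    if exact_counts:
        n_male = int(round(n * profile.male_fraction))
    else:
        n_male = int(rng.binomial(n, profile.male_fraction))
    sexes = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(sexes)
    ages = profile.age_law.sample(n, rng)
    tiv = np.empty(n)
    male = sexes == "male"
    tiv[male] = profile.tiv_law_male.sample(int(male.sum()), rng)
    tiv[~male] = profile.tiv_law_female.sample(int((~male).sum()), rng)
    width = len(str(n))
    return [
        SubjectRecord(
            subject_id=f"sub-{profile.name}{i:0{width}d}",
            sex=str(sexes[i]),
            age_years=float(ages[i]),
            tiv_ml=float(tiv[i]),
            cohort_label=profile.name,
        )
        for i in range(n)
    ]


def build_atlas(
    grid_dims: tuple[int, int, int] = DESK_GRID,
    n_regions: int = 17,
    seed: int = 0,
    *,
    voxel_size_mm: float | None = None,
) -> ROIAtlas:
    """Partition an ellipsoidal brain mask into nearest-seed regions.

    The mask is the interior of the ellipsoid inscribed in the grid (axes
    at 90% of the half-extents).  ``n_regions`` seed voxels are drawn
    uniformly from the mask and every mask voxel is assigned to its nearest
    seed (Euclidean; ties to the lowest region label), yielding contiguous,
    pairwise-disjoint regions covering the mask.
    """
    if n_regions < 1:
        raise ValueError("need at least one region")
    nx, ny, nz = grid_dims
    if voxel_size_mm is None:
        voxel_size_mm = FULL_VOXEL_MM * FULL_GRID[0] / nx
    center = (np.array(grid_dims) - 1) / 2.0
    semi = 0.9 * (np.array(grid_dims) / 2.0)
    ix, iy, iz = np.indices(grid_dims)
    r2 = (((ix - center[0]) / semi[0]) ** 2
          + ((iy - center[1]) / semi[1]) ** 2
          + ((iz - center[2]) / semi[2]) ** 2)
    mask = r2 <= 1.0
    coords = np.argwhere(mask)
    if n_regions > len(coords):
        raise ValueError(
            f"n_regions={n_regions} exceeds mask voxel count {len(coords)}")
    rng = np.random.default_rng(seed)
    seed_idx = rng.choice(len(coords), size=n_regions, replace=False)
    seeds = coords[seed_idx]
    # nearest-seed assignment; argmin takes the lowest label on ties
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1) + 1
    label_grid = np.zeros(grid_dims, dtype=np.int16)
    label_grid[tuple(coords.T)] = assign
    if n_regions * 8 > len(coords):
        raise ValueError("grid too small: fewer than 8 voxels per region")
    table = {i + 1: f"region_{i + 1:02d}" for i in range(n_regions)}
    return ROIAtlas(label_grid=label_grid, label_table=table,
                    voxel_size_mm=float(voxel_size_mm))


def _expected_regional_volumes(record: SubjectRecord,
                               effects: EffectSpec) -> np.ndarray:
    scale = (record.tiv_ml / effects.tiv_ref_ml) ** effects.tiv_exponent
    sex_mult = 1.0 + effects.sex_effect * (record.sex == "female")
    vols = effects.base_volume_ml * scale * sex_mult
    if np.any(vols <= 0):
        raise ValueError("non-positive expected regional volume")
    return vols


def synthesize_image(
    record: SubjectRecord,
    atlas: ROIAtlas,
    effects: EffectSpec,
    seed: int,
) -> GMVImage:
    """Generate one subject's image from the regional volume laws."""
    if effects.n_regions != atlas.n_regions:
        raise ValueError("atlas and effects disagree on the region set")
    vols = _expected_regional_volumes(record, effects)
    rng = np.random.default_rng(seed)
    if effects.subject_sd > 0:
        vols = vols * rng.lognormal(0.0, effects.subject_sd)
    if effects.region_sd > 0:
        vols = vols * rng.lognormal(0.0, effects.region_sd,
                                    size=effects.n_regions)
    values = np.zeros(atlas.grid_dims, dtype=np.float64)
    for i in range(atlas.n_regions):
        region = atlas.label_grid == (i + 1)
        n_vox = int(region.sum())
        per_voxel = vols[i] / n_vox
        v = np.full(n_vox, per_voxel)
        if effects.noise_sd_ml > 0:
            v = v + rng.normal(0.0, effects.noise_sd_ml, size=n_vox)
            np.clip(v, 0.0, None, out=v)
        values[region] = v
    return GMVImage(values=values.astype(np.float32), subject_id=record.subject_id)


def simulate_cohort(
    profile: CohortProfile,
    seed: int,
    *,
    atlas: ROIAtlas | None = None,
    effects: EffectSpec | None = None,
    n: int | None = None,
    grid_dims: tuple[int, int, int] = DESK_GRID,
    n_regions: int = 17,
) -> Cohort:
    """Simulate a full cohort (records, images, atlas) under one seed.

    Atlas, effect spec, demographics and per-subject image noise all derive
    from ``seed`` through independent spawned streams, so identical inputs
    reproduce identical cohorts.
    """
    if n is not None:
        profile = dataclasses.replace(profile, n=n)
    ss = np.random.SeedSequence(seed)
    s_atlas, s_eff, s_demo, s_img = (int(c.generate_state(1)[0] % (2**31))
                                     for c in ss.spawn(4))
    if atlas is None:
        atlas = build_atlas(grid_dims, n_regions, s_atlas)
    if effects is None:
        effects = default_effects(atlas, profile, s_eff)
    records = sample_demographics(profile, s_demo)
    images = np.empty((len(records),) + atlas.grid_dims, dtype=np.float32)
    img_rng = np.random.SeedSequence(s_img)
    for i, (rec, child) in enumerate(zip(records, img_rng.spawn(len(records)))):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        images[i] = synthesize_image(rec, atlas, effects, child_seed).values
    gmv = images.reshape(len(records), -1).sum(axis=1).astype(np.float64)
    return Cohort(records=records, images=images, atlas=atlas,
                  effects=effects, gmv_ml=gmv)


def save_profile(profile: CohortProfile, path: str | Path) -> None:
    """Serialize a cohort profile to YAML."""
    d = dataclasses.asdict(profile)
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def load_profile(path: str | Path) -> CohortProfile:
    """Load a cohort profile from a YAML file."""
    d = yaml.safe_load(Path(path).read_text())
    for key in ("age_law", "tiv_law_male", "tiv_law_female"):
        d[key] = TruncNormLaw(**d[key])
    return CohortProfile(**d)


def _affine(voxel_size_mm: float) -> np.ndarray:
    aff = np.diag([voxel_size_mm, voxel_size_mm, voxel_size_mm, 1.0])
    return aff


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict[str, Path]:
    """Write per-subject NIfTI images, the atlas and a participants table."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(cohort.atlas.voxel_size_mm)
    paths: dict[str, Path] = {}
    for rec, img in zip(cohort.records, cohort.images):
        if img.shape != cohort.atlas.grid_dims:
            raise ValueError("image/atlas dimension mismatch")
        p = out / f"{rec.subject_id}_gmv.nii.gz"
        nib.save(nib.Nifti1Image(img.astype(np.float32), aff), p)
        paths[rec.subject_id] = p
    atlas_path = out / "atlas.nii.gz"
    nib.save(nib.Nifti1Image(cohort.atlas.label_grid.astype(np.int16), aff),
             atlas_path)
    paths["atlas"] = atlas_path
    df = cohort.frame()
    tsv = out / "participants.tsv"
    df.to_csv(tsv, sep="\t", index=False)
    paths["participants"] = tsv
    return paths


def read_cohort(out_dir: str | Path) -> tuple[pd.DataFrame, np.ndarray, ROIAtlas]:
    """Read back a written cohort: (participants frame, image stack, atlas)."""
    out = Path(out_dir)
    df = pd.read_csv(out / "participants.tsv", sep="\t")
    atlas_img = nib.load(out / "atlas.nii.gz")
    label_grid = np.asarray(atlas_img.dataobj).astype(np.int16)
    voxel_size = float(atlas_img.header.get_zooms()[0])
    labels = np.unique(label_grid[label_grid > 0])
    table = {int(l): f"region_{int(l):02d}" for l in labels}
    atlas = ROIAtlas(label_grid=label_grid, label_table=table,
                     voxel_size_mm=voxel_size)
    images = np.empty((len(df),) + atlas.grid_dims, dtype=np.float32)
    for i, sid in enumerate(df["subject_id"]):
        images[i] = np.asarray(
            nib.load(out / f"{sid}_gmv.nii.gz").dataobj, dtype=np.float32)
    return df, images, atlas
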