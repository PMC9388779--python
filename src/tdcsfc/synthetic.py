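"""Synthetic cohort generator for the rs-FC treatment-response pipeline.

Real patient data for this design are not distributable, so every downstream stage is
exercised on simulated cohorts that carry the statistical structure the
analysis assumes:

* a desk-scale brain (nested ellipsoids: CSF core, white-matter shell,
  gray-matter shell) parcellated into contiguous angular-sector regions;
* region-level latent BOLD signals (unit-variance AR(1)), with the latents of
  designated *discriminative* regions coupled to the seed-home latent at a
  class-dependent correlation (responders vs. non-responders);
* shared WM/CSF nuisance components mixed into gray matter, white voxel
  noise, motion series and global-signal spikes for the QC stage;
* clinical covariates drawn to match the responder / non-responder group
  summaries of the reference demographic table, with the responder label
  reproducible from the generated pre/post hallucination scores;
* a disjoint pre-training cohort (healthy controls, first-degree relatives,
  schizophrenia and OCD patients) with CGI severity scores and reduced-grid
  FC volumes for transfer learning.

Everything is deterministic given ``(config, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Optional, Sequence

import numpy as np

from .types import AtlasParcellation, BoldSeries, SubjectRecord

__all__ = [
    "SimConfig",
    "PretrainCohortSpec",
    "PretrainRecord",
    "SimulatedSubject",
    "CLINICAL_GROUP_STATS",
    "make_atlas",
    "make_subject_bold",
    "make_cohort",
    "iter_cohort",
    "make_pretrain_cohort",
    "make_qc_fixture_cohort39",
    "resolve_discriminative_regions",
]

#: AR(1) lag-1 coefficient of all latent signals (rs-fMRI-like autocorrelation).
AR1_COEF = 0.3

#: Weight at which each shared nuisance component (WM, CSF) enters gray matter.
NUISANCE_WEIGHT = 0.2


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator.

    ``rho_responder`` / ``rho_nonresponder`` are the target correlations
    between the seed-home latent and the latents of the discriminative
    regions; the defaults (0.6 / 0.2) give the class contrast the recovery
    analyses use.  ``spike_amplitude`` is expressed in units of the
    baseline scan-to-scan global-signal SD (the scale the scrubbing z-score
    uses) and is injected uniformly into all in-brain voxels at each spike
    volume.
    """

    grid_dims: tuple[int, int, int] = (24, 28, 24)
    voxel_size_mm: float = 4.0
    n_volumes: int = 150
    tr_s: float = 2.0
    rho_responder: float = 0.6
    rho_nonresponder: float = 0.2
    discriminative_regions: Optional[tuple[int, ...]] = None
    noise_sd: float = 1.0
    n_spikes: int = 1
    spike_amplitude: float = 6.0
    seed: int = 0
    n_regions: int = 10
    grid_center_mm: tuple[float, float, float] = (-10.0, 0.0, 0.0)
    seed_center_mm: tuple[float, float, float] = (-48.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if any(d < 8 for d in self.grid_dims):
            raise ValueError("grid_dims must all be >= 8")
        for rho in (self.rho_responder, self.rho_nonresponder):
            if not (0 <= abs(rho) < 1):
                raise ValueError("|rho| must be in [0, 1)")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.n_volumes < 3:
            raise ValueError("n_volumes must be >= 3")
        if self.n_regions < 8:
            raise ValueError("at least 8 atlas regions are required")

    @classmethod
    def full_scale(cls, **kwargs) -> "SimConfig":
        """Full-resolution variant: 91x109x91 at 2 mm on the standard grid."""
        kwargs.setdefault("grid_dims", (91, 109, 91))
        kwargs.setdefault("voxel_size_mm", 2.0)
        kwargs.setdefault("grid_center_mm", (0.0, -18.0, 18.0))
        return cls(**kwargs)

    @property
    def affine(self) -> np.ndarray:
        v = self.voxel_size_mm
        dims = np.asarray(self.grid_dims, dtype=float)
        center = np.asarray(self.grid_center_mm, dtype=float)
        aff = np.diag([v, v, v, 1.0])
        aff[:3, 3] = center - v * (dims - 1) / 2.0
        return aff


@dataclass(frozen=True)
class PretrainCohortSpec:
    """Composition of the disjoint pre-training cohort.

    Healthy controls (HC) and unaffected first-degree relatives (FDR) carry
    CGI 0; schizophrenia (SZ) and OCD patients are at least moderately ill
    (CGI drawn from {4, 5, 6}).  FC volumes are generated on a reduced grid.
    """

    n_hc: int = 186
    n_fdr: int = 62
    n_sz: int = 44
    n_ocd: int = 149
    grid_dims: tuple[int, int, int] = (16, 16, 16)
    n_volumes: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_hc, self.n_fdr, self.n_sz, self.n_ocd) < 0:
            raise ValueError("cohort counts must be >= 0")


@dataclass
class PretrainRecord:
    record_id: str
    group: str  # HC | FDR | SZ | OCD
    cgi: int
    sex: int
    age: float
    fc_volume: np.ndarray


@dataclass
class SimulatedSubject:
    """One simulated subject with its generative ground truth attached."""

    bold: BoldSeries
    tissue_masks: dict[str, np.ndarray]
    latents: dict[int, np.ndarray]  # region label -> latent series
    spike_volumes: np.ndarray


# Reference group summaries (mean, sd) for the clinical covariates; keys match
# SubjectRecord fields.  Sex is the male:female ratio.
CLINICAL_GROUP_STATS: dict[str, dict[str, tuple[float, float]]] = {
    "responder": {
        "age": (30.06, 7.89),
        "education_years": (14.11, 1.71),
        "duration_untreated_months": (12.88, 23.86),
        "duration_illness_months": (105.88, 88.39),
        "olanzapine_equiv": (15.68, 8.98),
        "pre_saps": (44.47, 19.66),
        "pre_sans": (38.35, 20.89),
        "pre_madrs": (13.47, 7.01),
        "pre_psyrats": (31.0, 4.74),
        "percent_improvement": (47.7, 17.0),
    },
    "nonresponder": {
        "age": (32.23, 7.47),
        "education_years": (13.70, 1.67),
        "duration_untreated_months": (9.35, 15.14),
        "duration_illness_months": (106.23, 71.16),
        "olanzapine_equiv": (22.70, 16.67),
        "pre_saps": (31.06, 12.36),
        "pre_sans": (16.94, 12.58),
        "pre_madrs": (10.25, 5.67),
        "pre_psyrats": (29.82, 5.84),
        "percent_improvement": (10.4, 8.0),
    },
}

SEX_MALE_PROB = {"responder": 7 / 17, "nonresponder": 12 / 17}

_PLAUSIBLE_RANGES: dict[str, tuple[float, float]] = {
    "age": (18.0, 48.0),
    "education_years": (5.0, 24.0),
    "duration_untreated_months": (0.0, 120.0),
    "duration_illness_months": (3.0, 360.0),
    "olanzapine_equiv": (0.0, 80.0),
    "pre_saps": (0.0, 170.0),
    "pre_sans": (0.0, 125.0),
    "pre_madrs": (0.0, 60.0),
    "pre_psyrats": (8.0, 44.0),
    "percent_improvement": (-25.0, 95.0),
}


# ---------------------------------------------------------------------------
# geometry


def _mm_coords(config: SimConfig) -> np.ndarray:
    """(X, Y, Z, 3) array of voxel-center mm coordinates."""
    idx = np.indices(config.grid_dims, dtype=float)
    aff = config.affine
    coords = np.einsum("ij,j...->...i", aff[:3, :3], idx) + aff[:3, 3]
    return coords


def _ellipsoid(coords: np.ndarray, center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    return (((coords - center) / semi) ** 2).sum(axis=-1) <= 1.0


def tissue_geometry(config: SimConfig) -> dict[str, np.ndarray]:
    """Boolean gray/WM/CSF masks from nested ellipsoids."""
    coords = _mm_coords(config)
    fov = config.voxel_size_mm * np.asarray(config.grid_dims, dtype=float)
    center = np.asarray(config.grid_center_mm, dtype=float)
    brain = _ellipsoid(coords, center, 0.45 * fov)
    inner = _ellipsoid(coords, center, 0.28 * fov)
    csf = _ellipsoid(coords, center, 0.10 * fov)
    return {"gray": brain & ~inner, "wm": inner & ~csf, "csf": csf, "brain": brain}


def make_atlas(config: SimConfig) -> AtlasParcellation:
    """Parcellate the gray-matter shell into contiguous angular sectors.

    Regions are azimuthal wedges split into superior/inferior halves (both
    connected on the shell); the wedge boundaries are rotated by a seeded
    offset so different seeds give different atlases.  The region containing
    the seed coordinate is designated seed-home.
    """
    tissues = tissue_geometry(config)
    gray = tissues["gray"]
    coords = _mm_coords(config)
    center = np.asarray(config.grid_center_mm, dtype=float)

    n_az = config.n_regions // 2
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    offset = rng.uniform(0, 2 * np.pi / n_az)

    rel = coords - center
    azimuth = np.mod(np.arctan2(rel[..., 1], rel[..., 0]) + offset, 2 * np.pi)
    az_bin = np.minimum((azimuth / (2 * np.pi / n_az)).astype(int), n_az - 1)
    upper = (rel[..., 2] >= 0).astype(int)

    labels = np.zeros(config.grid_dims, dtype=np.int32)
    labels[gray] = (az_bin * 2 + upper + 1)[gray]

    present = sorted(int(l) for l in np.unique(labels) if l != 0)
    if len(present) < config.n_regions:
        raise ValueError(
            f"grid {config.grid_dims} too small to host {config.n_regions} "
            f"non-empty regions (got {len(present)})"
        )

    inv = np.linalg.inv(config.affine)
    seed_vox = np.round(inv[:3, :3] @ np.asarray(config.seed_center_mm) + inv[:3, 3]).astype(int)
    if np.any(seed_vox < 0) or np.any(seed_vox >= np.asarray(config.grid_dims)):
        raise ValueError("seed coordinate falls outside the grid")
    seed_home = int(labels[tuple(seed_vox)])
    if seed_home == 0:
        raise ValueError("seed coordinate is not inside gray matter")

    names = {lab: f"region_{lab:02d}" for lab in present}
    names[seed_home] = "seed_home_LSTG"
    return AtlasParcellation(
        labels=labels, affine=config.affine, names=names, seed_home_label=seed_home
    )


def resolve_discriminative_regions(
    atlas: AtlasParcellation, config: SimConfig
) -> tuple[int, ...]:
    """Atlas labels that carry the class effect (default: first two
    non-seed-home labels)."""
    if config.discriminative_regions is not None:
        regions = tuple(config.discriminative_regions)
        for lab in regions:
            if lab not in atlas.names:
                raise ValueError(f"unknown discriminative region label {lab}")
            if lab == atlas.seed_home_label:
                raise ValueError("seed-home region cannot be discriminative")
        return regions
    return tuple(l for l in atlas.region_labels if l != atlas.seed_home_label)[:2]


# ---------------------------------------------------------------------------
# BOLD simulation


def _ar1(rng: np.random.Generator, n: int, phi: float = AR1_COEF) -> np.ndarray:
    """Unit-marginal-variance stationary AR(1) series."""
    x = np.empty(n)
    x[0] = rng.standard_normal()
    innov = rng.standard_normal(n - 1) * math.sqrt(1 - phi**2)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + innov[t - 1]
    return x


def make_subject_bold(
    atlas: AtlasParcellation,
    is_responder: bool,
    config: SimConfig,
    subject_seed: int,
    motion_violation_fraction: float = 0.0,
) -> SimulatedSubject:
    """Simulate one subject's 4D BOLD series on the atlas grid.

    Voxel series = region latent + white noise; the latent of each
    discriminative region is ``rho * seed_latent + sqrt(1 - rho^2) * e`` with
    ``e`` an independent unit-variance AR(1) process, so its population
    correlation with the seed-home latent is exactly ``rho``.  WM and CSF
    voxels are driven by shared nuisance components that also leak into gray
    matter at weight ``NUISANCE_WEIGHT``.  Spikes add
    ``spike_amplitude * sd(diff(global signal))`` to every in-brain voxel at seeded
    volumes; ``motion_violation_fraction > 0`` plants composite-motion
    excursions >= 2.5 mm at that fraction of volumes (QC fixtures).
    """
    if atlas.labels.shape != config.grid_dims:
        raise ValueError("atlas and config grids differ")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(subject_seed)]))
    T = config.n_volumes
    rho = config.rho_responder if is_responder else config.rho_nonresponder
    disc = resolve_discriminative_regions(atlas, config)

    seed_latent = _ar1(rng, T)
    latents: dict[int, np.ndarray] = {}
    for lab in atlas.region_labels:
        if lab == atlas.seed_home_label:
            latents[lab] = seed_latent
        else:
            latents[lab] = _ar1(rng, T)
    for lab in disc:
        latents[lab] = rho * seed_latent + math.sqrt(1 - rho**2) * latents[lab]

    tissues = tissue_geometry(config)
    brain = tissues["brain"]
    u_wm = _ar1(rng, T)
    u_csf = _ar1(rng, T)

    data = np.zeros(config.grid_dims + (T,), dtype=np.float32)
    for lab in atlas.region_labels:
        mask = atlas.labels == lab
        n_vox = int(mask.sum())
        series = (
            latents[lab]
            + NUISANCE_WEIGHT * (u_wm + u_csf)
            + config.noise_sd * rng.standard_normal((n_vox, T))
        )
        data[mask] = series.astype(np.float32)
    for comp, mask in (("wm", tissues["wm"]), ("csf", tissues["csf"])):
        n_vox = int(mask.sum())
        u = u_wm if comp == "wm" else u_csf
        data[mask] = (u + config.noise_sd * rng.standard_normal((n_vox, T))).astype(
            np.float32
        )

    # spikes: uniform offset to all in-brain voxels, scaled by the baseline
    # scan-to-scan global-signal SD (the scale the scrubbing z-score uses)
    spike_volumes = np.array([], dtype=int)
    if config.n_spikes > 0:
        spike_volumes = np.sort(
            rng.choice(np.arange(2, T - 1), size=config.n_spikes, replace=False)
        )
        diff_sd = float(np.diff(data[brain].mean(axis=0)).std())
        for t in spike_volumes:
            data[..., t][brain] += config.spike_amplitude * diff_sd

    # motion: small random walk, optionally with planted >=2.5 mm excursions
    increments = rng.normal(0.0, 0.05, size=(T, 6))
    increments[:, 3:] /= 50.0  # rotations in rad; ~same mm scale on a 50 mm sphere
    increments[0] = 0.0
    if motion_violation_fraction > 0:
        n_bad = math.ceil(motion_violation_fraction * T)
        bad = rng.choice(np.arange(1, T), size=n_bad, replace=False)
        increments[bad, 0] = 2.5 * rng.choice([-1.0, 1.0], size=n_bad)
    motion = np.cumsum(increments, axis=0)

    bold = BoldSeries(
        data=data,
        affine=config.affine,
        tr_s=config.tr_s,
        motion=motion,
        brain_mask=brain,
        subject_id=f"sub-{subject_seed:03d}",
    )
    masks = {k: tissues[k] for k in ("gray", "wm", "csf")}
    return SimulatedSubject(
        bold=bold, tissue_masks=masks, latents=latents, spike_volumes=spike_volumes
    )


# ---------------------------------------------------------------------------
# clinical covariates


from functools import lru_cache


@lru_cache(maxsize=None)
def _recentred_loc(mean: float, sd: float, lo: float, hi: float) -> float:
    """Location of the underlying normal such that the [lo, hi]-truncated
    distribution has mean ``mean`` (fixed point, 4 iterations)."""
    from scipy.stats import truncnorm

    loc = mean
    for _ in range(4):
        a, b = (lo - loc) / sd, (hi - loc) / sd
        loc = loc - (truncnorm.mean(a, b, loc=loc, scale=sd) - mean)
    return loc


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float
) -> float:
    """Draw from a truncated normal whose *truncated* mean equals ``mean``,
    so truncation to the plausible range does not bias group means away from
    the target summary statistics."""
    from scipy.stats import truncnorm

    loc = _recentred_loc(mean, sd, lo, hi)
    a, b = (lo - loc) / sd, (hi - loc) / sd
    return float(truncnorm.rvs(a, b, loc=loc, scale=sd, random_state=rng))


def _sample_record(
    rng: np.random.Generator, group: str, subject_id: str
) -> SubjectRecord:
    stats = CLINICAL_GROUP_STATS[group]
    vals = {}
    for key, (m, s) in stats.items():
        lo, hi = _PLAUSIBLE_RANGES[key]
        if key == "percent_improvement":
            # enforce the responder rule by construction
            lo, hi = (25.0, 95.0) if group == "responder" else (-25.0, 24.999)
        vals[key] = _truncated_normal(rng, m, s, lo, hi)
    imp = vals.pop("percent_improvement")
    pre = vals["pre_psyrats"]
    post = pre * (1.0 - imp / 100.0)
    return SubjectRecord(
        subject_id=subject_id,
        sex=int(rng.random() < SEX_MALE_PROB[group]),
        post_psyrats=post,
        intended_responder=(group == "responder"),
        **vals,
    )


def iter_cohort(
    n_responders: int,
    n_nonresponders: int,
    config: SimConfig,
    atlas: Optional[AtlasParcellation] = None,
) -> Iterator[tuple[SubjectRecord, SimulatedSubject]]:
    """Stream (record, simulated subject) pairs; memory stays O(1 subject)."""
    if n_responders < 1 or n_nonresponders < 1:
        raise ValueError("cohort needs at least one subject per class")
    if atlas is None:
        atlas = make_atlas(config)
    clin_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 104729]))
    groups = ["responder"] * n_responders + ["nonresponder"] * n_nonresponders
    for i, group in enumerate(groups):
        record = _sample_record(clin_rng, group, f"sub-{i:03d}")
        sim = make_subject_bold(atlas, group == "responder", config, subject_seed=i)
        yield record, sim


def make_cohort(
    n_responders: int, n_nonresponders: int, config: SimConfig
) -> list[tuple[SubjectRecord, BoldSeries]]:
    """Materialized cohort of (clinical record, BOLD series) pairs."""
    return [(rec, sim.bold) for rec, sim in iter_cohort(n_responders, n_nonresponders, config)]


# ---------------------------------------------------------------------------
# pre-training cohort


def make_pretrain_cohort(spec: PretrainCohortSpec) -> list[PretrainRecord]:
    """Disjoint multi-diagnosis cohort with CGI scores and reduced-grid FC maps.

    HC/FDR records are generated with healthy-level seed coupling, SZ/OCD with
    reduced coupling, so the CGI-derived pre-training labels are learnable
    from the FC volumes.  Labels themselves are assigned later by
    :func:`tdcsfc.cnn_transfer.assign_cgi_labels`.
    """
    from .connectivity import SeedSpec, make_sphere_mask, seed_fc_map

    cfg = SimConfig(
        grid_dims=spec.grid_dims,
        voxel_size_mm=6.0,
        n_volumes=spec.n_volumes,
        grid_center_mm=(-10.0, 0.0, 0.0),
        seed_center_mm=(-45.0, 0.0, 0.0),
        n_spikes=0,
        seed=spec.seed,
        n_regions=8,
    )
    atlas = make_atlas(cfg)
    seed_spec = SeedSpec(center_mni_mm=cfg.seed_center_mm, radius_mm=12.0)
    sphere = make_sphere_mask(seed_spec, cfg.grid_dims, cfg.affine)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 15485863]))

    records: list[PretrainRecord] = []
    counts = [("HC", spec.n_hc), ("FDR", spec.n_fdr), ("SZ", spec.n_sz), ("OCD", spec.n_ocd)]
    idx = 0
    for group, n in counts:
        healthy = group in ("HC", "FDR")
        sub_cfg = replace(
            cfg,
            rho_responder=0.5 if healthy else 0.15,
            rho_nonresponder=0.5 if healthy else 0.15,
        )
        for _ in range(n):
            cgi = 0 if healthy else int(rng.choice([4, 5, 6]))
            sim = make_subject_bold(atlas, True, sub_cfg, subject_seed=idx)
            fc = seed_fc_map(sim.bold, sphere)
            records.append(
                PretrainRecord(
                    record_id=f"pre-{idx:03d}",
                    group=group,
                    cgi=cgi,
                    sex=int(rng.random() < 0.5),
                    age=float(np.clip(rng.normal(32.0, 9.0), 18.0, 60.0)),
                    fc_volume=fc.z_values.astype(np.float32),
                )
            )
            idx += 1
    return records


# ---------------------------------------------------------------------------
# QC fixture


def make_qc_fixture_cohort39(
    seed: int, config: Optional[SimConfig] = None
) -> list[tuple[SubjectRecord, BoldSeries, bool]]:
    """Fixture of 39 subjects mirroring a realistic QC attrition flow.

    Exactly 2 subjects are flagged as registration failures and exactly 3 are
    planted with motion artifacts dense enough that >= 30% of their volumes
    exceed the outlier thresholds; the remaining 34 pass both checks by
    construction.
    """
    if config is None:
        config = SimConfig(seed=seed)
    atlas = make_atlas(config)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 32452843]))
    flagged = rng.choice(39, size=5, replace=False)
    reg_fail = set(int(i) for i in flagged[:2])
    censor_fail = set(int(i) for i in flagged[2:])
    clin_rng = np.random.default_rng(np.random.SeedSequence([seed, 49979687]))

    out = []
    for i in range(39):
        group = "responder" if i % 2 == 0 else "nonresponder"
        record = _sample_record(clin_rng, group, f"qc-{i:02d}")
        frac = 0.40 if i in censor_fail else 0.0
        sim = make_subject_bold(
            atlas, group == "responder", config, subject_seed=1000 + i,
            motion_violation_fraction=frac,
        )
        out.append((record, sim.bold, i not in reg_fail))
    return out
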