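"""Synthetic pre/post resting-state cohorts.

The generator emulates a two-group (treatment vs. sham), two-session
(pre/post) design: each subject-session-ROI carries a band-limited
signal — a sum of sinusoids with frequencies inside the 0.01-0.08 Hz
low-frequency band — on top of broadband white noise.  A treatment
effect is injected by multiplying the in-band amplitude by
``effect_size`` in the post session of treatment-group subjects, only
inside the designated effect ROIs.  Because fALFF is a spectral ratio,
this construction makes injected effects analytically interpretable:
fALFF responds monotonically to the in-band amplitude.

Hunger/satiety ratings (VAS, 14 cm scale) are coupled linearly to the
subject's delta-zfALFF in a chosen ROI, with a group-interaction term,
so the regression stage has a known ground truth to recover.

Two output modes: small 4D voxel grids (exercising sphere extraction at
desk scale) or direct per-ROI time series (fast statistical testing).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .falff import LOW_FREQ_BAND, VolumeSeries, falff, falff_map, session_difference, zscore_map
from .roi import ROISet, extract_features

__all__ = [
    "RatingModel",
    "CohortSpec",
    "Subject",
    "Cohort",
    "generate_timeseries",
    "generate_cohort",
    "cohort_features",
    "write_cohort",
]

TREATMENT, SHAM = "tVNS", "sham"

#: reserved name prefix for the background z-scoring bank (series mode)
BACKGROUND_PREFIX = "bg-"


@dataclass(frozen=True)
class RatingModel:
    """Linear coupling of a rating difference to one ROI's delta-zfALFF.

    rating_diff = intercept + slope * x + interaction * treated * x + noise,
    where x is the subject's delta-zfALFF in ``roi`` and treated is 0/1.
    """

    roi: str
    slope: float = 0.0
    interaction: float = 0.0
    intercept: float = 0.0
    noise_sd: float = 1.0


@dataclass(frozen=True)
class CohortSpec:
    """Study-design parameters for a synthetic cohort.

    Defaults mirror the emulated acquisition: 320 volumes at TR 1.5 s
    (eight minutes), of which the first 10 are conventionally discarded
    by the reader before analysis.
    """

    n_per_group: int
    rois: Sequence[str] | ROISet
    n_volumes: int = 320
    dt: float = 1.5
    grid_shape: tuple[int, int, int] | None = None
    voxel_size: float = 3.0
    effect_rois: tuple[str, ...] = ()
    effect_size: float = 1.0
    band_amplitude: float = 1.0
    #: stable regional heterogeneity: per-ROI base amplitudes span this
    #: multiplicative range (catalog order), shared by all subjects and
    #: sessions.  Real regions differ in their spontaneous fluctuation
    #: amplitude; without this spread, z-scoring across ROIs would divide
    #: by pure sampling noise.
    roi_amplitude_range: tuple[float, float] = (0.6, 1.4)
    #: between-subject/-session variability: each subject-session-ROI band
    #: amplitude is multiplied by exp(N(0, subject_sd)).  In resting-state
    #: cohorts this idiosyncratic variance dominates group effects (the
    #: subject spread of delta-zfALFF typically exceeds the group median
    #: difference), so a moderate effect does not saturate classification.
    subject_sd: float = 0.35
    #: series mode only: number of background reference series generated
    #: per session and used solely as the z-scoring context.  Voxelwise
    #: zfALFF is normalised over a whole-brain mask in which the analysis
    #: ROIs are a negligible fraction; without this bank, z-scoring across
    #: the handful of analysis ROIs alone would redistribute an injected
    #: contrast into the non-effect ROIs (sum-zero coupling).
    n_background: int = 30
    noise_sd: float = 1.0
    n_sinusoids: int = 8
    rating_models: Mapping[str, RatingModel] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_volumes <= 10:
            raise ValueError("n_volumes must exceed the 10 discarded volumes")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.effect_size <= 0:
            raise ValueError("effect_size must be positive")
        names = self.roi_names
        if len(set(names)) != len(names):
            raise ValueError("ROI names must be unique")
        if any(n.startswith(BACKGROUND_PREFIX) for n in names):
            raise ValueError(
                f"ROI names must not start with {BACKGROUND_PREFIX!r}")
        if self.n_background < 0:
            raise ValueError("n_background must be non-negative")
        missing = set(self.effect_rois) - set(names)
        if missing:
            raise ValueError(f"effect_rois not in the ROI catalog: {sorted(missing)}")
        if self.grid_shape is not None and not isinstance(self.rois, ROISet):
            raise ValueError("volume mode needs a ROISet with coordinates")
        if self.rating_models:
            for m in self.rating_models.values():
                if m.roi not in names:
                    raise ValueError(f"rating model ROI {m.roi!r} not in catalog")

    @property
    def roi_names(self) -> list[str]:
        return self.rois.names if isinstance(self.rois, ROISet) else list(self.rois)


@dataclass
class Subject:
    subject_id: str
    group: str  # TREATMENT or SHAM
    #: session -> (roi -> 1d series) in series mode, or VolumeSeries
    sessions: dict


@dataclass
class Cohort:
    spec: CohortSpec
    subjects: list[Subject]
    phenotypes: pd.DataFrame  # subject_id, group, hunger/satiety pre+post

    @property
    def groups(self) -> dict[str, str]:
        return {s.subject_id: s.group for s in self.subjects}


def generate_timeseries(
    n_volumes: int,
    dt: float,
    band_amplitude: float,
    broadband_sd: float,
    rng: np.random.Generator,
    n_sinusoids: int = 8,
) -> np.ndarray:
    """A band-limited signal plus white noise.

    The signal is a sum of ``n_sinusoids`` sinusoids with frequencies
    drawn uniformly inside the low-frequency band and random phases,
    scaled so its total variance is ``band_amplitude**2``; the noise is
    Gaussian with SD ``broadband_sd``.  Draw order is fixed, so the same
    generator state yields the same frequencies, phases and noise
    regardless of the amplitude parameters.
    """
    if n_volumes <= 0:
        raise ValueError("n_volumes must be positive")
    if dt <= 0:
        raise ValueError("dt must be positive")
    lo, hi = LOW_FREQ_BAND
    freqs = rng.uniform(lo, hi, size=n_sinusoids)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=n_sinusoids)
    noise = rng.normal(0.0, 1.0, size=n_volumes)
    t = np.arange(n_volumes) * dt
    per_sin = band_amplitude * np.sqrt(2.0 / n_sinusoids)
    signal = per_sin * np.sin(
        2.0 * np.pi * freqs[:, None] * t[None, :] + phases[:, None]
    ).sum(axis=0)
    return signal + broadband_sd * noise


def _grid_affine(shape: tuple[int, int, int], voxel_size: float) -> np.ndarray:
    """RAS affine centring the grid on MNI (0, 0, 0)."""
    affine = np.eye(4)
    affine[:3, :3] *= voxel_size
    affine[:3, 3] = -(np.asarray(shape) - 1) / 2.0 * voxel_size
    return affine


def _band_amp(spec: CohortSpec, group: str, session: str, roi: str) -> float:
    names = spec.roi_names
    lo, hi = spec.roi_amplitude_range
    profile = np.linspace(lo, hi, len(names))
    amp = spec.band_amplitude * profile[names.index(roi)]
    if group == TREATMENT and session == "post" and roi in spec.effect_rois:
        amp *= spec.effect_size
    return amp


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate a balanced two-group, two-session cohort.

    Deterministic given the spec (including its seed): each
    subject-session draws from its own child stream in a fixed order.
    """
    ss = np.random.SeedSequence(spec.seed)
    n_subj = 2 * spec.n_per_group
    # one child per subject-session plus one for ratings and pre-baselines
    children = ss.spawn(2 * n_subj + 1)
    rating_rng = np.random.default_rng(children[-1])

    subjects: list[Subject] = []
    names = spec.roi_names
    for i in range(n_subj):
        group = TREATMENT if i < spec.n_per_group else SHAM
        sid = f"sub-{i + 1:03d}"
        sessions: dict = {}
        for j, session in enumerate(("pre", "post")):
            rng = np.random.default_rng(children[2 * i + j])
            if spec.grid_shape is None:
                series = {}
                for roi in names:
                    jitter = np.exp(rng.normal(0.0, spec.subject_sd))
                    series[roi] = generate_timeseries(
                        spec.n_volumes, spec.dt,
                        _band_amp(spec, group, session, roi) * jitter,
                        spec.noise_sd, rng, spec.n_sinusoids)
                lo, hi = spec.roi_amplitude_range
                bg_profile = np.linspace(lo, hi, max(spec.n_background, 1))
                for k in range(spec.n_background):
                    jitter = np.exp(rng.normal(0.0, spec.subject_sd))
                    amp = spec.band_amplitude * bg_profile[k] * jitter
                    series[f"{BACKGROUND_PREFIX}{k:02d}"] = generate_timeseries(
                        spec.n_volumes, spec.dt, amp, spec.noise_sd, rng,
                        spec.n_sinusoids)
                sessions[session] = series
            else:
                sessions[session] = _volume_session(spec, group, session, rng)
        subjects.append(Subject(sid, group, sessions))

    cohort = Cohort(spec=spec, subjects=subjects, phenotypes=pd.DataFrame())
    cohort.phenotypes = _generate_phenotypes(cohort, rating_rng)
    return cohort


def _volume_session(spec: CohortSpec, group: str, session: str,
                    rng: np.random.Generator) -> VolumeSeries:
    """A small 4D grid: per-voxel noise plus, inside each ROI sphere, a
    band-limited signal shared by the ROI's voxels (spatial coherence)."""
    assert isinstance(spec.rois, ROISet) and spec.grid_shape is not None
    shape = tuple(spec.grid_shape)
    affine = _grid_affine(shape, spec.voxel_size)
    data = rng.normal(0.0, spec.noise_sd, size=shape + (spec.n_volumes,))
    for r in spec.rois:
        jitter = np.exp(rng.normal(0.0, spec.subject_sd))
        amp = _band_amp(spec, group, session, r.name) * jitter
        # signal drawn even when amplitude is unchanged, keeping draw
        # order identical across conditions
        sig = generate_timeseries(spec.n_volumes, spec.dt, amp, 0.0, rng,
                                  spec.n_sinusoids)
        m = r.mask(shape, affine)
        data[m] += sig
    return VolumeSeries(data, dt=spec.dt, affine=affine, n_discarded=0)


def cohort_features(
    cohort: Cohort,
    discard: int = 10,
    band: tuple[float, float] = LOW_FREQ_BAND,
    ratio: str = "sum",
) -> pd.DataFrame:
    """Subjects x ROIs delta-zfALFF feature table (plus ``group``).

    The first ``discard`` volumes are dropped before spectral analysis
    (the reader's dummy-scan removal).  In series mode, fALFF is
    computed per ROI and z-scored across the ROI set within each
    session — the ROI-granularity analogue of voxelwise zfALFF; in
    volume mode, voxelwise fALFF maps are z-scored within the grid mask
    and ROI means are extracted from the post-pre difference map.
    """
    spec = cohort.spec
    names = spec.roi_names
    if spec.grid_shape is None:
        rows = {}
        for s in cohort.subjects:
            per_session = {}
            for session in ("pre", "post"):
                all_names = list(s.sessions[session])
                vals = np.array([
                    falff(s.sessions[session][roi][discard:], spec.dt,
                          band=band, ratio=ratio)[1]
                    for roi in all_names
                ])
                # z-reference includes the background bank, mirroring the
                # voxelwise mask in which analysis ROIs are a small part
                z = (vals - vals.mean()) / vals.std()
                per_session[session] = dict(zip(all_names, z))
            rows[s.subject_id] = {
                roi: per_session["post"][roi] - per_session["pre"][roi]
                for roi in names
            }
        table = pd.DataFrame.from_dict(rows, orient="index")[names]
        table.index.name = "subject_id"
        table["group"] = [s.group for s in cohort.subjects]
        return table

    maps = {}
    for s in cohort.subjects:
        z = {}
        for session in ("pre", "post"):
            vol = s.sessions[session]
            trimmed = VolumeSeries(vol.data[..., discard:], dt=vol.dt,
                                   affine=vol.affine, n_discarded=discard)
            z[session] = zscore_map(falff_map(trimmed, band=band, ratio=ratio))
        maps[s.subject_id] = session_difference(z["post"], z["pre"])
    return extract_features(maps, spec.rois, groups=cohort.groups)


def _generate_phenotypes(cohort: Cohort, rng: np.random.Generator) -> pd.DataFrame:
    """VAS ratings per session; differences follow the rating models."""
    spec = cohort.spec
    models = dict(spec.rating_models or {
        "hunger": RatingModel(roi=spec.roi_names[0]),
        "satiety": RatingModel(roi=spec.roi_names[-1]),
    })
    features = cohort_features(cohort)
    rows = []
    for s in cohort.subjects:
        treated = 1 if s.group == TREATMENT else 0
        row = {"subject_id": s.subject_id, "group": s.group}
        for scale, m in models.items():
            x = features.loc[s.subject_id, m.roi]
            diff = (m.intercept + m.slope * x + m.interaction * treated * x
                    + rng.normal(0.0, m.noise_sd))
            pre = float(np.clip(rng.normal(7.0, 2.0), 0.0, 14.0))
            row[f"{scale}_pre"] = pre
            row[f"{scale}_post"] = pre + diff
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort(cohort: Cohort, outdir: str | Path) -> None:
    """Write a cohort to disk: NIfTI volumes (volume mode) or per-ROI
    series CSVs (series mode), a phenotype CSV, and the ROI catalog TSV."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    spec = cohort.spec
    for s in cohort.subjects:
        for session in ("pre", "post"):
            if spec.grid_shape is None:
                df = pd.DataFrame(s.sessions[session])
                df.to_csv(out / f"{s.subject_id}_{session}_roiseries.csv",
                          index=False)
            else:
                s.sessions[session].to_nifti(
                    out / f"{s.subject_id}_{session}_bold.nii.gz")
    cohort.phenotypes.to_csv(out / "phenotypes.csv", index=False)
    if isinstance(spec.rois, ROISet):
        spec.rois.to_tsv(out / "roi_catalog.tsv")
    else:
        pd.DataFrame({"name": spec.roi_names}).to_csv(
            out / "roi_catalog.tsv", sep="\t", index=False)
    manifest = {"n_per_group": spec.n_per_group, "n_volumes": spec.n_volumes,
                "dt": spec.dt, "effect_rois": list(spec.effect_rois),
                "effect_size": spec.effect_size, "seed": spec.seed}
    (out / "cohort.json").write_text(json.dumps(manifest, indent=2))
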