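"""Deterministic longitudinal dual-contrast brain-phantom simulator.

The simulator emulates the *structure* of a longitudinal infant imaging
cohort — per subject: T1-like and T2-like volumes at two ages ("6m", "12m")
with per-tissue ground-truth labels, overall growth between the ages,
myelination-like contrast change, and a configurable fraction of subjects
missing one timepoint — without any anatomical realism.  Geometry is a set
of nested ellipsoids (CSF shell ⊃ cortical GM shell ⊃ WM core ⊃ deep GM)
plus six mirrored pairs of small subcortical blobs, so both a "tissue" and
a "subcortical" evaluation task exist.

Myelination is emulated qualitatively: in T1-like images the WM/GM
intensity gap is small at 6m and large at 12m, and the relationship is
inverted in T2-like images.  The default tissue table also makes at least
one tissue pair better separated in T2 than in T1 at 6m, so dual-contrast
input genuinely carries complementary information.

Everything is a pure function of (spec, seeds): identical inputs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .errors import ConfigError, DataError
from .volume_io import (
    LabelMap,
    Volume,
    normalize_intensity,
    read_label_map,
    read_volume,
    write_label_map,
    write_volume,
)

__all__ = [
    "TissueParams",
    "PhantomSpec",
    "SubjectRecord",
    "Cohort",
    "generate_subject",
    "generate_cohort",
    "save_cohort",
    "load_cohort",
    "segment_by_intensity",
]

AGES = ("6m", "12m")
CONTRASTS = ("T1w", "T2w")


@dataclass(frozen=True)
class TissueParams:
    """Mean intensity (arbitrary units, background = 0) per contrast and age."""

    name: str
    label: int
    means: dict  # {(contrast, age): mean}
    noise_sd: float = 2.0


def _blob(name, label, t1_6, t1_12, t2_6, t2_12, sd=2.0):
    return TissueParams(
        name,
        label,
        {
            ("T1w", "6m"): t1_6,
            ("T1w", "12m"): t1_12,
            ("T2w", "6m"): t2_6,
            ("T2w", "12m"): t2_12,
        },
        sd,
    )


def default_tissues() -> tuple[TissueParams, ...]:
    """Default tissue intensity table.

    T1-like: WM barely brighter than cortical GM at 6m (gap 5), clearly
    brighter at 12m (gap 20) — myelination.  T2-like: WM brighter than GM at
    6m (gap 10, larger than the T1 gap: complementary contrast) and darker
    at 12m.  Subcortical structures sit around the deep-GM intensity with
    pairwise-distinct offsets; pallidum myelinates earliest (brightest T1
    at 12m).
    """
    return (
        _blob("CSF", 1, 20.0, 20.0, 95.0, 95.0),
        _blob("cortical_GM", 2, 55.0, 55.0, 70.0, 66.0),
        _blob("WM", 3, 50.0, 75.0, 80.0, 55.0),
        _blob("deep_GM", 4, 60.0, 65.0, 66.0, 61.0),
        _blob("caudate", 5, 58.0, 62.0, 68.0, 63.0),
        _blob("putamen", 6, 61.0, 66.0, 65.0, 60.0),
        _blob("pallidum", 7, 66.0, 72.0, 62.0, 56.0),
        _blob("thalamus", 8, 63.0, 70.0, 64.0, 58.0),
        _blob("amygdala", 9, 57.0, 60.0, 69.0, 64.0),
        _blob("hippocampus", 10, 56.0, 59.0, 71.0, 65.0),
    )


# Subcortical blob geometry in units of the 6m brain semi-axes (fractions of
# the outer ellipsoid), mirrored across the sagittal midplane.  Offsets keep
# the blobs inside the WM core (core ~ 0.75 of the outer shell).
_BLOB_GEOMETRY = {
    "caudate": ((0.18, 0.26, 0.10), 0.090),
    "putamen": ((0.30, 0.05, 0.02), 0.095),
    "pallidum": ((0.30, -0.12, -0.07), 0.090),
    "thalamus": ((0.20, -0.26, 0.05), 0.110),
    "amygdala": ((0.38, -0.24, -0.22), 0.090),
    "hippocampus": ((0.30, -0.38, -0.08), 0.090),
}


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry, intensity and randomness settings of the phantom cohort.

    shape axes must each be divisible by 8 so that the three 2x
    downsamplings of the generator are exact.  growth_factor is the linear
    (radius) scale from 6m to 12m; the default 1.08 corresponds to the
    roughly 25% brain-volume increase seen over the second half of the
    first year.
    """

    shape: tuple[int, int, int] = (32, 32, 32)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tissues: tuple[TissueParams, ...] = field(default_factory=default_tissues)
    growth_factor: float = 1.08
    smoothing_fwhm: float = 1.0
    jitter: float = 0.03  # per-subject relative variation of semi-axes
    seed: int = 0

    def __post_init__(self):
        if len(self.shape) != 3 or any(s % 8 != 0 or s < 8 for s in self.shape):
            raise ConfigError(
                f"phantom shape axes must be >= 8 and divisible by 8, got {self.shape}"
            )
        if not self.growth_factor > 1:
            raise ConfigError("growth_factor must be > 1")
        if any(t.noise_sd < 0 for t in self.tissues):
            raise ConfigError("tissue noise sds must be >= 0")
        if self.smoothing_fwhm < 0:
            raise ConfigError("smoothing_fwhm must be >= 0")
        for contrast in CONTRASTS:
            for age in AGES:
                means = [t.means[(contrast, age)] for t in self.tissues]
                if len(set(means)) != len(means):
                    raise ConfigError(
                        f"tissue means must be pairwise distinct ({contrast}, {age})"
                    )

    @property
    def label_names(self) -> dict[int, str]:
        names = {}
        for t in self.tissues:
            if t.label <= 4:
                names[t.label] = t.name
            else:
                names[2 * t.label - 5] = f"{t.name}_L"
                names[2 * t.label - 4] = f"{t.name}_R"
        return names


@dataclass
class SubjectRecord:
    """One subject: per age a pair of contrasts plus a label map.

    ``missing_tag`` names the absent timepoint (or None); ``imputed`` lists
    age tags whose scans were filled in by a trained model rather than
    "acquired".
    """

    subject_id: str
    scans: dict  # {age: {contrast: Volume}}
    labels: dict  # {age: LabelMap}
    missing_tag: str | None = None
    imputed: set = field(default_factory=set)

    def __post_init__(self):
        if not self.scans:
            raise DataError(f"{self.subject_id}: at least one timepoint required")

    @property
    def present_ages(self) -> list[str]:
        return [a for a in AGES if a in self.scans]

    def is_complete(self) -> bool:
        return all(a in self.scans for a in AGES)


@dataclass
class Cohort:
    records: list
    split: dict  # subject_id -> "train" | "val" | "test"
    spec: PhantomSpec

    def subjects(self, split: str | None = None) -> list:
        if split is None:
            return list(self.records)
        return [r for r in self.records if self.split[r.subject_id] == split]


def _ellipsoid_mask(shape, center, semi_axes):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = 0.0
    for g, c, a in zip(grids, center, semi_axes):
        acc = acc + ((g - c) / a) ** 2
    return acc <= 1.0


def _subject_labels(spec: PhantomSpec, semi_axes, age_scale: float) -> np.ndarray:
    """Voxelise nested shells + mirrored blobs at one age."""
    shape = spec.shape
    center = tuple((s - 1) / 2.0 for s in shape)
    ax = tuple(a * age_scale for a in semi_axes)
    labels = np.zeros(shape, dtype=np.int16)
    outer = _ellipsoid_mask(shape, center, ax)
    gm_shell = _ellipsoid_mask(shape, center, tuple(0.90 * a for a in ax))
    wm_core = _ellipsoid_mask(shape, center, tuple(0.74 * a for a in ax))
    deep = _ellipsoid_mask(shape, center, tuple(0.26 * a for a in ax))
    labels[outer] = 1  # CSF
    labels[gm_shell] = 2  # cortical GM
    labels[wm_core] = 3  # WM
    labels[deep] = 4  # deep GM
    by_name = {t.name: t for t in spec.tissues}
    for name, (offset, rad_frac) in _BLOB_GEOMETRY.items():
        t = by_name[name]
        radius = tuple(rad_frac * a for a in ax)
        for side, sign in (("L", -1.0), ("R", 1.0)):
            c = (
                center[0] + sign * offset[0] * ax[0],
                center[1] + offset[1] * ax[1],
                center[2] + offset[2] * ax[2],
            )
            blob = _ellipsoid_mask(shape, c, radius)
            label = 2 * t.label - 5 if side == "L" else 2 * t.label - 4
            labels[blob & (labels == 3)] = label
    return labels


def _blob_tissue_of_label(spec: PhantomSpec, label: int) -> TissueParams:
    if label <= 4:
        return next(t for t in spec.tissues if t.label == label)
    base = (label + 5) // 2 if label % 2 else (label + 4) // 2
    return next(t for t in spec.tissues if t.label == base)


def _render(spec: PhantomSpec, labels: np.ndarray, contrast: str, age: str,
            rng: np.random.Generator) -> np.ndarray:
    """Paint tissue means onto the label grid, add noise, blur."""
    img = np.zeros(spec.shape, dtype=np.float64)
    for label in np.unique(labels):
        if label == 0:
            continue
        t = _blob_tissue_of_label(spec, int(label))
        mask = labels == label
        img[mask] = t.means[(contrast, age)]
        if t.noise_sd > 0:
            img[mask] += rng.normal(0.0, t.noise_sd, size=int(mask.sum()))
    if spec.smoothing_fwhm > 0:
        sigma = [spec.smoothing_fwhm / 2.3548 / s for s in spec.spacing]
        brain = labels > 0
        img = gaussian_filter(img, sigma=sigma)
        # keep the far background exactly zero so normalisation can pin it
        halo = gaussian_filter(brain.astype(np.float64), sigma=sigma) > 1e-6
        img[~halo] = 0.0
    img[img < 0] = 0.0
    return img


def generate_subject(spec: PhantomSpec, subject_seed: int) -> SubjectRecord:
    """Simulate one subject: two ages x two contrasts + label maps.

    The 12m geometry is the 6m geometry scaled by ``growth_factor`` about
    the volume centre.  Per-subject semi-axes are jittered around 0.82 of
    the half-grid (leaving room for growth).  Deterministic in
    (spec, subject_seed).
    """
    ss = np.random.SeedSequence([spec.seed, int(subject_seed)])
    rng_geom, rng_noise = [np.random.default_rng(s) for s in ss.spawn(2)]
    base = tuple(0.82 * (s - 1) / 2.0 / spec.growth_factor for s in spec.shape)
    semi_axes = tuple(
        a * (1.0 + spec.jitter * rng_geom.uniform(-1.0, 1.0)) for a in base
    )
    scans: dict = {}
    labels: dict = {}
    for age, scale in zip(AGES, (1.0, spec.growth_factor)):
        lab = _subject_labels(spec, semi_axes, scale)
        labels[age] = LabelMap(lab, spec.spacing, spec.label_names)
        scans[age] = {}
        for contrast in CONTRASTS:
            raw = _render(spec, lab, contrast, age, rng_noise)
            vol = Volume(raw, spec.spacing, contrast=contrast, age_tag=age)
            scans[age][contrast] = normalize_intensity(vol)
    return SubjectRecord(f"sub-{subject_seed:04d}", scans, labels)


def _split_counts(n: int, proportions) -> tuple[int, int, int]:
    if abs(sum(proportions) - 1.0) > 1e-9:
        raise ConfigError(f"split proportions must sum to 1, got {proportions}")
    n_val = round(n * proportions[1])
    n_test = round(n * proportions[2])
    n_train = n - n_val - n_test
    if n_train < 1:
        raise ConfigError("split leaves no training subjects")
    return n_train, n_val, n_test


def generate_cohort(
    spec: PhantomSpec,
    n_subjects: int,
    missing_fraction: float = 0.0,
    split=(0.8, 0.1, 0.1),
) -> Cohort:
    """Simulate a cohort with split assignment and structured missingness.

    Exactly ``round(missing_fraction * n_subjects)`` subjects lose one
    timepoint, alternating 6m / 12m so both prediction directions stay
    exercised; incomplete subjects are always placed in the training split
    (predicted scans must never reach evaluation data).
    """
    if n_subjects < 3:
        raise ConfigError("need at least 3 subjects")
    if not (0.0 <= missing_fraction < 1.0):
        raise ConfigError("missing_fraction must be in [0, 1)")
    n_train, n_val, n_test = _split_counts(n_subjects, split)
    n_missing = round(missing_fraction * n_subjects)
    if n_missing > n_train:
        raise ConfigError(
            f"{n_missing} incomplete subjects cannot all fit in a train split of {n_train}"
        )
    records = [generate_subject(spec, i) for i in range(n_subjects)]
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 987654321]))
    order = rng.permutation(n_subjects)
    split_of: dict = {}
    # incomplete subjects are drawn first and forced into train
    for k, idx in enumerate(order[:n_missing]):
        rec = records[idx]
        drop = AGES[k % 2]
        rec.scans.pop(drop)
        rec.labels.pop(drop, None)
        rec.missing_tag = drop
        split_of[rec.subject_id] = "train"
    remaining = list(order[n_missing:])
    n_train_left = n_train - n_missing
    for pos, idx in enumerate(remaining):
        if pos < n_train_left:
            split_of[records[idx].subject_id] = "train"
        elif pos < n_train_left + n_val:
            split_of[records[idx].subject_id] = "val"
        else:
            split_of[records[idx].subject_id] = "test"
    return Cohort(records, split_of, spec)


def save_cohort(cohort: Cohort, out_dir) -> Path:
    """Write the cohort as a NIfTI directory tree + manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in cohort.records:
        sdir = out_dir / rec.subject_id
        sdir.mkdir(exist_ok=True)
        for age in rec.present_ages:
            for contrast, vol in rec.scans[age].items():
                p = sdir / f"{rec.subject_id}_{age}_{contrast}.nii.gz"
                write_volume(vol, p)
                rows.append(
                    dict(
                        subject_id=rec.subject_id,
                        age_tag=age,
                        contrast=contrast,
                        path=str(p.relative_to(out_dir)),
                        split=cohort.split[rec.subject_id],
                        missing_tag=rec.missing_tag or "",
                        imputed=age in rec.imputed,
                    )
                )
            if age in rec.labels:
                write_label_map(rec.labels[age], sdir / f"{rec.subject_id}_{age}_labels.nii.gz")
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    return out_dir


def load_cohort(in_dir, spec: PhantomSpec | None = None) -> Cohort:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv", keep_default_na=False)
    split: dict = {}
    records: list = []
    for sid, rows in manifest.groupby("subject_id", sort=False):
        scans: dict = {}
        labels: dict = {}
        imputed: set = set()
        for _, row in rows.iterrows():
            scans.setdefault(row["age_tag"], {})[row["contrast"]] = read_volume(
                in_dir / row["path"])
            if bool(row["imputed"]):
                imputed.add(row["age_tag"])
            lab_path = in_dir / sid / f"{sid}_{row['age_tag']}_labels.nii.gz"
            if lab_path.exists() and row["age_tag"] not in labels:
                labels[row["age_tag"]] = read_label_map(lab_path)
        split[sid] = rows["split"].iloc[0]
        missing = rows["missing_tag"].iloc[0] or None
        records.append(SubjectRecord(sid, scans, labels, missing_tag=missing,
                                     imputed=imputed))
    return Cohort(records, split, spec or PhantomSpec())


def segment_by_intensity(vol: Volume, spec: PhantomSpec, age: str) -> LabelMap:
    """Nearest-tissue-mean classifier for phantom images.

    A deliberately simple stand-in segmentation algorithm: each voxel is
    assigned the phantom label whose normalised mean intensity (for the
    volume's contrast at ``age``) is closest, with an extra background
    class at -1.  Applying the *same* classifier to a predicted and a
    ground-truth image realises the segmentation-consistency protocol on
    phantom data.

    Known limitation: the darkest tissue of a contrast normalises to
    exactly -1, indistinguishable from stripped background, so it is
    absorbed into the background class (for T1-like phantoms: CSF).  Both
    sides of a consistency comparison are affected identically; the
    structure surfaces as an undefined row in the metric report.
    """
    if not vol.normalized:
        raise DataError("segment_by_intensity expects a normalized volume")
    means = {t.label: t.means[(vol.contrast, age)] for t in spec.tissues}
    lo, hi = min(means.values()), max(means.values())
    centers = [-1.0] + [2.0 * (m - lo) / (hi - lo) - 1.0 for m in means.values()]
    base_labels = [0] + list(means.keys())
    data = np.asarray(vol.data, dtype=np.float64)
    dist = np.stack([np.abs(data - c) for c in centers])
    nearest = np.argmin(dist, axis=0)
    seg = np.zeros(vol.shape, dtype=np.int16)
    for i, lab in enumerate(base_labels):
        seg[nearest == i] = lab
    # split paired subcortical labels by hemisphere (left = lower x index)
    out = np.zeros_like(seg)
    mid = vol.shape[0] / 2.0
    xs = np.arange(vol.shape[0])[:, None, None]
    left = np.broadcast_to(xs < mid, vol.shape)
    for lab in np.unique(seg):
        if lab <= 4:
            out[seg == lab] = lab
        else:
            out[(seg == lab) & left] = 2 * lab - 5
            out[(seg == lab) & ~left] = 2 * lab - 4
    return LabelMap(out, vol.spacing, spec.label_names)
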