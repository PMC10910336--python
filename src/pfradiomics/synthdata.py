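"""Synthetic lateral-knee cohorts with planted prognostic signal.

Each subject gets a latent severity s ~ Uniform(0,1) that simultaneously
drives

* patella shape — a rotated superellipse whose vertical elongation and
  inferior-pole protrusion grow with s (morphology carries signal),
* peri-trochlear texture — a spatially correlated Gaussian random field,
  windowed to a band posterior-inferior to the patella (so signal exists
  outside the bone, where the inferior ROI reaches),
* the Kellgren-Lawrence grade — a monotone noisy mapping of s onto 0..4,
  calibrated to the grade proportions of a large osteoarthritis cohort
  (45% / 17.7% / 14.9% / 15.0% / 7.4% for grades 0-4), and
* the knee-replacement hazard — a proportional-hazards Weibull model
  (shape 2 by default, so progression speed tracks severity rather than
  exponential happenstance) with log-hazard
  alpha + severity_effect*s + klg_effect*KLG, per-subject administrative
  censoring Uniform(84, 101) months plus occasional early dropout,
  calibrated so ~10.5% of subjects have a KR event by 84 months.

Demographics (age, gender, BMI) are independent of the hazard.  All knees
are generated as left; right-knee support is a mirror flip.  Everything is
deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy import ndimage

from .imageprep import PatellaMask, Radiograph, make_rois, mask_bbox

# frozen Monte-Carlo calibrations (see docs/methods.md):
# noisy-severity cutpoints reproducing the target KLG proportions ...
KLG_THRESHOLDS = (0.4316, 0.6756, 0.9110, 1.2746)
KLG_NOISE_SD = 0.45
# ... and the baseline log-hazard giving a 10.5% 84-month event fraction
# under the default effect sizes.
BASELINE_LOG_HAZARD = -15.2315

COHORT_COLUMNS = ["subject_id", "age", "gender", "bmi", "klg", "pfoa",
                  "kr_event", "kr_time_months", "laterality"]


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort."""
    n_subjects: int = 100
    seed: int = 0
    image_size_px: tuple[int, int] = (192, 224)       # rows, cols
    pixel_spacing_mm: float = 0.35
    event_rate_target: float = 0.105                  # 84-month event fraction
    severity_effect: float = 3.0                      # log-hazard slope of s
    klg_effect: float = 1.0                           # log-hazard slope per grade
    baseline_log_hazard: float = BASELINE_LOG_HAZARD
    admin_censor_months: tuple[float, float] = (84.0, 101.0)
    dropout_prob: float = 0.05
    weibull_shape: float = 2.0
    texture_contrast_range: tuple[float, float] = (0.02, 0.25)
    patella_elongation_range: tuple[float, float] = (1.0, 1.12)
    inferior_osteophyte_range: tuple[float, float] = (0.0, 3.0)   # mm

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if not (0.0 < self.event_rate_target < 1.0):
            raise ValueError("event_rate_target must be in (0,1)")
        if self.image_size_px[0] < 64 or self.image_size_px[1] < 64:
            raise ValueError("image too small to contain patella plus the "
                             "posterior ROI extension")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel spacing must be positive")
        for rng_ in (self.texture_contrast_range,
                     self.patella_elongation_range,
                     self.inferior_osteophyte_range,
                     self.admin_censor_months):
            if rng_[0] > rng_[1]:
                raise ValueError(f"interval {rng_} has lower > upper")


@dataclass
class SubjectRecord:
    subject_id: str
    age: float
    gender: str                       # "male" / "female"
    bmi: float
    klg: int
    pfoa: float                       # 0.0 / 1.0 / nan (missing)
    kr_event: int
    kr_time_months: float
    laterality: str = "left"

    def __post_init__(self) -> None:
        if self.kr_time_months <= 0:
            raise ValueError("follow-up time must be positive")
        if self.klg not in range(5):
            raise ValueError("KLG must be in 0..4")


def records_to_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in records], columns=COHORT_COLUMNS)


def frame_to_records(df: pd.DataFrame) -> list[SubjectRecord]:
    return [SubjectRecord(str(r.subject_id), float(r.age), str(r.gender),
                          float(r.bmi), int(r.klg), float(r.pfoa),
                          int(r.kr_event), float(r.kr_time_months),
                          str(r.laterality))
            for r in df.itertuples(index=False)]


def _lerp(interval: tuple[float, float], u: float) -> float:
    return interval[0] + (interval[1] - interval[0]) * u


# --------------------------------------------------------------------------
# tabular simulation
# --------------------------------------------------------------------------

def severity_to_klg(severity: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    z = severity + rng.normal(0.0, KLG_NOISE_SD, severity.size)
    return np.digitize(z, KLG_THRESHOLDS).astype(int)


def simulate_table(config: SimulationConfig,
                   rng: np.random.Generator | None = None
                   ) -> tuple[pd.DataFrame, np.ndarray]:
    """Draw the cohort table; returns (table, latent severity)."""
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    n = config.n_subjects
    s = rng.uniform(0.0, 1.0, n)
    klg = severity_to_klg(s, rng)
    age = np.clip(rng.normal(62.4, 8.0, n), 50.0, 79.0)
    gender = np.where(rng.random(n) < 0.6, "male", "female")
    bmi = np.clip(rng.normal(30.5, 5.0, n), 17.0, 58.0)
    pfoa = (s + rng.normal(0.0, 0.4, n) > 0.75).astype(float)
    pfoa[rng.random(n) < 0.068] = np.nan

    lam = np.exp(config.baseline_log_hazard + config.severity_effect * s
                 + config.klg_effect * klg)
    k = config.weibull_shape
    T = rng.exponential(1.0, n) ** (1.0 / k) / lam ** (1.0 / k)
    admin = rng.uniform(*config.admin_censor_months, n)
    drop = np.where(rng.random(n) < config.dropout_prob,
                    rng.uniform(1.0, config.admin_censor_months[0], n), np.inf)
    C = np.minimum(admin, drop)
    event = (T <= C).astype(int)
    t_obs = np.maximum(np.minimum(T, C), 1e-3)

    df = pd.DataFrame({
        "subject_id": [f"S{i:05d}" for i in range(n)],
        "age": np.round(age, 1),
        "gender": gender,
        "bmi": np.round(bmi, 1),
        "klg": klg,
        "pfoa": pfoa,
        "kr_event": event,
        "kr_time_months": np.round(t_obs, 3),
        "laterality": "left",
    }, columns=COHORT_COLUMNS)
    return df, s


# --------------------------------------------------------------------------
# image rendering
# --------------------------------------------------------------------------

def _gaussian_random_field(shape, corr_len_px: float,
                           rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, shape)
    f = ndimage.gaussian_filter(noise, sigma=corr_len_px, mode="reflect")
    sd = f.std()
    return f / sd if sd > 0 else f


def render_subject(severity: float, config: SimulationConfig,
                   rng: np.random.Generator) -> tuple[Radiograph, PatellaMask]:
    """Render one left lateral knee: bright convex patella on a darker,
    textured background, with severity-scaled shape and texture signal."""
    nr, nc = config.image_size_px
    sp = config.pixel_spacing_mm
    rows, cols = np.mgrid[0:nr, 0:nc].astype(np.float64)

    # --- patella geometry (superellipse, slightly rotated) ---
    cr = 0.45 * nr + rng.uniform(-4, 4)
    cc = 0.40 * nc + rng.uniform(-4, 4)
    # anatomical size varies for non-disease reasons (body size): a global
    # jitter larger than the severity-driven elongation keeps ROI area from
    # acting as a severity proxy in every ROI
    size = rng.uniform(0.90, 1.10)
    elong = _lerp(config.patella_elongation_range, severity) * rng.uniform(0.98, 1.02)
    a_px = 14.0 * size * elong / sp                # vertical semi-axis
    b_px = (9.5 * size + rng.uniform(-0.6, 0.6)) / sp   # horizontal semi-axis
    theta = np.deg2rad(rng.uniform(-12.0, 12.0))
    dr = rows - cr
    dc = cols - cc
    u = np.cos(theta) * dr - np.sin(theta) * dc    # along the long axis
    v = np.sin(theta) * dr + np.cos(theta) * dc
    p_exp = 2.5
    body = (np.abs(u / a_px) ** p_exp + np.abs(v / b_px) ** p_exp) <= 1.0

    # inferior-pole protrusion, length scaled by severity
    osteo_mm = _lerp(config.inferior_osteophyte_range, severity) \
        + rng.uniform(0.0, 0.5)
    lobe = np.zeros_like(body)
    if osteo_mm > 0.2:
        L = osteo_mm / sp
        tip_u, tip_v = a_px * 0.92, 0.25 * b_px    # slightly posterior tip
        lobe = (((u - tip_u) / L) ** 2 + ((v - tip_v) / (3.0 / sp)) ** 2) <= 1.0
    mask = body | lobe
    if not mask.any():
        raise ValueError("patella rasterized to an empty mask")

    # --- intensities (arbitrary scale; normalization removes it) ---
    img = 0.22 + 0.05 * (cols / nc)
    img = img + 0.02 * _gaussian_random_field((nr, nc), 8.0, rng)

    # femoral condyle: broad bright disc posterior-inferior to the patella;
    # anchored in image coordinates so its edges carry no severity signal
    fr = cr + 16.0 / sp + rng.uniform(-3, 3)
    fc = cc + 23.0 / sp + rng.uniform(-3, 3)
    fd = np.sqrt(((rows - fr) / (30.0 / sp)) ** 2 + ((cols - fc) / (26.0 / sp)) ** 2)
    img = img + 0.16 * np.clip(1.0 - fd, 0.0, 1.0)

    # patella body: bright, with a faint cortical rim
    interior = np.abs(u / a_px) ** p_exp + np.abs(v / b_px) ** p_exp
    rim = np.exp(-((interior - 1.0) / 0.12) ** 2) * mask
    img = img + mask * (0.45 - 0.06 * np.clip(1.0 - interior, 0, 1)) + 0.05 * rim

    # peri-trochlear texture field in a posterior-inferior band; a sigmoid
    # gate keeps it strictly outside the patella bounding box so the
    # bbox-based normalization statistics stay severity-independent
    amp = _lerp(config.texture_contrast_range, severity)
    grf = _gaussian_random_field((nr, nc), rng.uniform(2.0, 6.0), rng)
    band = np.exp(-0.5 * (((rows - (cr + 0.95 * a_px)) / (0.50 * a_px)) ** 2
                          + ((cols - (cc + 2.1 * b_px)) / (1.2 * b_px)) ** 2))
    gate = 1.0 / (1.0 + np.exp(-(cols - (cc + 1.25 * b_px)) / (0.08 * b_px)))
    img = img + amp * grf * band * gate

    img = img + rng.normal(0.0, 0.015, (nr, nc))   # acquisition noise

    # collimation border (dark) and a lead side marker (overexposed):
    # both clip at +-6 SD after normalization, pinning the global intensity
    # range of every processed image to exactly [-6, 6]
    img[:, :4] = 0.0
    img[6:14, nc - 14:nc - 6] = 3.0

    pixels = np.round(np.clip(img, 0.0, 3.2) * 20000.0)
    radio = Radiograph(pixels, (sp, sp), "left")
    pmask = PatellaMask(mask)
    # reject geometries whose ROI extension would leave the image
    make_rois(mask_bbox(pmask), "left", image_shape=(nr, nc))
    return radio, pmask


def generate_cohort(config: SimulationConfig
                    ) -> tuple[list[SubjectRecord], list[Radiograph],
                               list[PatellaMask]]:
    """Full cohort: records plus one rendered image and mask per subject."""
    ss = np.random.SeedSequence(config.seed)
    table_ss, image_ss = ss.spawn(2)
    df, severity = simulate_table(config, np.random.default_rng(table_ss))
    records = frame_to_records(df)
    child_seeds = image_ss.spawn(config.n_subjects)
    images: list[Radiograph] = []
    masks: list[PatellaMask] = []
    for i in range(config.n_subjects):
        img, msk = render_subject(float(severity[i]), config,
                                  np.random.default_rng(child_seeds[i]))
        images.append(img)
        masks.append(msk)
    return records, images, masks


def generate_cohort_with_severity(config: SimulationConfig):
    """As ``generate_cohort`` but also returns the latent severity array
    (handy for planted-signal checks)."""
    ss = np.random.SeedSequence(config.seed)
    table_ss, image_ss = ss.spawn(2)
    df, severity = simulate_table(config, np.random.default_rng(table_ss))
    records = frame_to_records(df)
    child_seeds = image_ss.spawn(config.n_subjects)
    images, masks = [], []
    for i in range(config.n_subjects):
        img, msk = render_subject(float(severity[i]), config,
                                  np.random.default_rng(child_seeds[i]))
        images.append(img)
        masks.append(msk)
    return records, images, masks, severity


# --------------------------------------------------------------------------
# cohort I/O (16-bit PNG images + 8-bit PNG masks + CSV table + JSON manifest)
# --------------------------------------------------------------------------

def _write_nifti(path: Path, array: np.ndarray, spacing_mm) -> None:
    import nibabel as nib
    affine = np.diag([spacing_mm[1], spacing_mm[0], 1.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(array, dtype=np.float32).T, affine),
             str(path))


def _read_nifti(path: Path) -> tuple[np.ndarray, tuple[float, float]]:
    import nibabel as nib
    img = nib.load(str(path))
    zooms = img.header.get_zooms()
    # header zooms are float32; round off the representation error
    return np.asarray(img.dataobj, dtype=np.float64).T, \
        (round(float(zooms[1]), 6), round(float(zooms[0]), 6))


def write_cohort(records: list[SubjectRecord], images: list[Radiograph],
                 masks: list[PatellaMask], out_dir: str | Path,
                 image_format: str = "png") -> Path:
    """Write a cohort; images as 16-bit PNG (default) or NIfTI-1."""
    if not (len(records) == len(images) == len(masks)):
        raise ValueError("records, images and masks must align")
    if image_format not in ("png", "nifti"):
        raise ValueError(f"unknown image format {image_format!r}")
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    rows = []
    for rec, img, msk in zip(records, images, masks):
        if img.shape != msk.shape:
            raise ValueError(f"{rec.subject_id}: image/mask shape mismatch")
        px = img.pixels
        if image_format == "nifti":
            img_path = out / "images" / f"{rec.subject_id}.nii.gz"
            _write_nifti(img_path, px, img.spacing_mm)
        else:
            if px.min() < 0 or px.max() > 65535:
                raise ValueError(f"{rec.subject_id}: intensities outside uint16")
            img_path = out / "images" / f"{rec.subject_id}.png"
            iio.imwrite(img_path, np.round(px).astype(np.uint16))
        msk_path = out / "masks" / f"{rec.subject_id}.png"
        iio.imwrite(msk_path, (msk.pixels * 255).astype(np.uint8))
        rows.append({
            "subject_id": rec.subject_id,
            "image": str(img_path.relative_to(out)),
            "mask": str(msk_path.relative_to(out)),
            "spacing_mm": list(img.spacing_mm),
            "laterality": img.laterality,
        })
    records_to_frame(records).to_csv(out / "cohort.csv", index=False)
    manifest = {"format_version": 1, "table": "cohort.csv", "subjects": rows}
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def read_cohort(manifest_path: str | Path
                ) -> tuple[list[SubjectRecord], list[Radiograph],
                           list[PatellaMask]]:
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = json.loads(manifest_path.read_text())
    df = pd.read_csv(root / manifest["table"])
    records = frame_to_records(df)
    by_id = {row["subject_id"]: row for row in manifest["subjects"]}
    images, masks = [], []
    for rec in records:
        row = by_id.get(rec.subject_id)
        if row is None:
            raise FileNotFoundError(f"manifest lacks subject {rec.subject_id}")
        img_path = root / row["image"]
        msk_path = root / row["mask"]
        for p in (img_path, msk_path):
            if not p.exists():
                raise FileNotFoundError(
                    f"subject {rec.subject_id}: missing file {p}")
        if img_path.suffix in (".nii", ".gz"):
            pixels, spacing = _read_nifti(img_path)
        else:
            spacing = row.get("spacing_mm")
            if spacing is None:
                raise ValueError(
                    f"subject {rec.subject_id}: spacing metadata absent")
            pixels = iio.imread(img_path).astype(np.float64)
        images.append(Radiograph(pixels, tuple(spacing),
                                 row.get("laterality", "left")))
        masks.append(PatellaMask(iio.imread(msk_path) > 0))
    return records, images, masks
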