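"""Synthetic contrast-enhanced ultrasound (CEUS) video generator.

Real breast-CEUS datasets with metastasis labels are small, private and
expensive to annotate.  This module generates labelled CEUS-*like* clips with
the statistical structure the classifier relies on:

* a bright device/annotation band across the top of every frame,
* black margins surrounding a central imaging region filled with speckled
  tissue,
* an elliptical lesion whose intensity follows a class-dependent
  gamma-variate wash-in/wash-out enhancement curve (metastatic lesions wash
  in faster and enhance more strongly, a stylised form of the
  hypervascularity seen in aggressive tumours),
* one keyframe at peak enhancement, and
* class-conditional clinical attribute strings mirroring the four label
  categories used for auxiliary text.

It makes no claim of physical realism (no beamforming, no attenuation); its
job is to give the pipeline a controllable, reproducible signal.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

CLINICAL_CATEGORIES = (
    "Basic clinical data",
    "Histopathological biomarkers",
    "Contrast-enhanced ultrasound parameters",
    "Conventional ultrasound parameters",
)

# Class-conditional attribute tables.  The real study's clinical variables are
# not public; these placeholder vocabularies only need to be *correlated* with
# the class so that clinical-text conditioning is exercised end to end.
_ATTRIBUTE_TABLE: dict[str, tuple[list[str], list[float], list[float]]] = {
    # category -> (values, probs for class 0, probs for class 1)
    "Basic clinical data": (
        ["patient younger than 50 years", "patient 50 years or older"],
        [0.55, 0.45],
        [0.45, 0.55],
    ),
    "Histopathological biomarkers": (
        ["low ki-67 index", "high ki-67 index"],
        [0.7, 0.3],
        [0.3, 0.7],
    ),
    "Contrast-enhanced ultrasound parameters": (
        ["slow wash-in with mild enhancement", "rapid wash-in with marked enhancement"],
        [0.8, 0.2],
        [0.2, 0.8],
    ),
    "Conventional ultrasound parameters": (
        ["lesion with regular margin", "lesion with irregular margin"],
        [0.65, 0.35],
        [0.35, 0.65],
    ),
}


@dataclass(frozen=True)
class LesionKinetics:
    """Per-class enhancement-curve parameters (frame-index time units)."""

    rate_mean: float  # wash-in rate analog; time-to-peak = shape / rate
    rate_sd: float
    peak_intensity: float  # added on top of tissue, 0-255 scale
    onset_frame: int


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int = 60
    metastatic_fraction: float = 0.5
    n_frames: int = 120  # 2-minute clip analog
    frame_height: int = 128
    frame_width: int = 128
    band_height: int = 16
    band_intensity: float = 230.0
    tissue_intensity: float = 70.0
    margin: int = 16  # left/right black margin of the imaging region
    margin_top: int = 8  # gap between band and imaging region
    margin_bottom: int = 8
    lesion_params: dict[int, LesionKinetics] = field(
        default_factory=lambda: {
            0: LesionKinetics(rate_mean=0.08, rate_sd=0.015, peak_intensity=120.0, onset_frame=15),
            1: LesionKinetics(rate_mean=0.16, rate_sd=0.030, peak_intensity=170.0, onset_frame=15),
        }
    )
    shape_a: float = 2.0  # gamma-variate shape
    noise_sigma: float = 0.12  # multiplicative speckle scale
    seed: int = 0
    patient_prefix: str = "P"  # distinguishes disjoint cohorts (e.g. pretraining)

    def __post_init__(self):
        if self.n_frames < 11:
            raise ValueError("n_frames must be >= 11 to admit a +/-5 keyframe window")
        if not 0.0 < self.metastatic_fraction < 1.0:
            raise ValueError("metastatic_fraction must lie in (0, 1)")
        if set(self.lesion_params) != {0, 1}:
            raise ValueError("lesion_params must provide both classes 0 and 1")
        for kin in self.lesion_params.values():
            if kin.rate_mean <= 0 or kin.peak_intensity <= 0 or kin.peak_intensity > 255:
                raise ValueError("invalid lesion kinetics")

    def imaging_region(self) -> tuple[int, int, int, int]:
        """Ground-truth imaging rectangle as half-open (x0, y0, x1, y1)."""
        y0 = self.band_height + self.margin_top
        y1 = self.frame_height - self.margin_bottom
        x0 = self.margin
        x1 = self.frame_width - self.margin
        return (x0, y0, x1, y1)


@dataclass
class CeusSample:
    """One patient's clip: frames, reader keyframe, label, clinical text."""

    patient_id: str
    frames: np.ndarray  # (T, H, W) uint8
    keyframe_index: int
    class_label: int
    clinical_attributes: dict[str, str]

    def __post_init__(self):
        frames = np.asarray(self.frames)
        if frames.ndim != 3:
            raise ValueError("frames must be a (T, H, W) stack")
        if not 0 <= self.keyframe_index < frames.shape[0]:
            raise ValueError("keyframe_index out of range")
        if self.class_label not in (0, 1):
            raise ValueError("class_label must be 0 or 1")


def enhancement_curve(t, onset: float, rate: float, peak: float, shape_a: float = 2.0):
    """Gamma-variate bolus kinetics: 0 before onset, unique maximum ``peak``.

    I(t) = peak * tau**a * exp(a * (1 - tau)),  tau = (t - onset) / tp,

    with time-to-peak tp = shape_a / rate, so doubling the wash-in rate halves
    the time-to-peak.  Works elementwise on arrays of frame indices.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if not 0 < peak <= 255:
        raise ValueError("peak must lie in (0, 255]")
    t = np.asarray(t, dtype=np.float64)
    tp = shape_a / rate
    tau = (t - onset) / tp
    out = np.where(tau > 0, peak * np.abs(tau) ** shape_a * np.exp(shape_a * (1.0 - tau)), 0.0)
    if out.ndim == 0:
        return float(out)
    return out


def time_to_peak(rate: float, shape_a: float = 2.0) -> float:
    """Analytic argmax offset of :func:`enhancement_curve` (frames past onset)."""
    return shape_a / rate


def generate_dataset(config: SyntheticConfig) -> list[CeusSample]:
    """Generate ``config.n_patients`` labelled clips, one per patient.

    Class balance is exact: round(n_patients * metastatic_fraction) samples
    get label 1.  Fully reproducible from ``config.seed``.
    """
    n = config.n_patients
    if n < 2:
        raise ValueError("need at least 2 patients")
    n_pos = int(round(n * config.metastatic_fraction))
    if n_pos == 0 or n_pos == n:
        raise ValueError("both classes need at least one sample")

    rng = np.random.default_rng(config.seed)
    labels = np.array([1] * n_pos + [0] * (n - n_pos))
    rng.shuffle(labels)

    samples = []
    for i in range(n):
        patient_id = f"{config.patient_prefix}{i:04d}"
        samples.append(_render_patient(patient_id, int(labels[i]), config, rng))
    return samples


def _render_patient(patient_id: str, label: int, config: SyntheticConfig,
                    rng: np.random.Generator) -> CeusSample:
    H, W, T = config.frame_height, config.frame_width, config.n_frames
    x0, y0, x1, y1 = config.imaging_region()
    kin = config.lesion_params[label]

    rate = max(0.2 * kin.rate_mean, rng.normal(kin.rate_mean, kin.rate_sd))
    # lesion geometry: ellipse centred in the imaging region with mild jitter
    cx = (x0 + x1) / 2 + rng.uniform(-4, 4)
    cy = (y0 + y1) / 2 + rng.uniform(-4, 4)
    ax = (x1 - x0) * rng.uniform(0.26, 0.32)
    ay = (y1 - y0) * rng.uniform(0.20, 0.26)

    yy, xx = np.mgrid[0:H, 0:W]
    lesion = (((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2) <= 1.0

    base = np.zeros((H, W))
    base[: config.band_height, :] = config.band_intensity
    base[y0:y1, x0:x1] = config.tissue_intensity

    curve = enhancement_curve(
        np.arange(T), kin.onset_frame, rate, kin.peak_intensity, config.shape_a
    )
    frames = np.broadcast_to(base, (T, H, W)).copy()
    frames += lesion[None, :, :] * curve[:, None, None]

    if config.noise_sigma > 0:
        # multiplicative speckle, imaging region only (the annotation band is
        # an overlay, not an echo, and stays noise-free)
        noise = rng.normal(0.0, config.noise_sigma, size=(T, y1 - y0, x1 - x0))
        frames[:, y0:y1, x0:x1] *= 1.0 + noise

    frames = np.clip(frames, 0.0, 255.0).astype(np.uint8)

    lesion_mean = frames[:, lesion].mean(axis=1)
    keyframe = int(np.argmax(lesion_mean))

    attrs = {}
    for cat in CLINICAL_CATEGORIES:
        values, p0, p1 = _ATTRIBUTE_TABLE[cat]
        probs = p1 if label == 1 else p0
        attrs[cat] = values[rng.choice(len(values), p=probs)]

    return CeusSample(
        patient_id=patient_id,
        frames=frames,
        keyframe_index=keyframe,
        class_label=label,
        clinical_attributes=attrs,
    )


# -- on-disk layout ----------------------------------------------------------
def save_dataset(samples: list[CeusSample], out_dir: str | Path) -> Path:
    """Write one directory per patient (numbered PNGs + JSON sidecar) and a
    top-level ``manifest.csv``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in samples:
        pdir = out_dir / s.patient_id
        pdir.mkdir(exist_ok=True)
        for t, frame in enumerate(s.frames):
            iio.imwrite(pdir / f"frame_{t:04d}.png", frame)
        sidecar = {
            "patient_id": s.patient_id,
            "keyframe_index": s.keyframe_index,
            "class_label": s.class_label,
            "clinical_attributes": s.clinical_attributes,
        }
        (pdir / "sample.json").write_text(json.dumps(sidecar, indent=2))
        rows.append((s.patient_id, s.patient_id, s.class_label))
    with open(out_dir / "manifest.csv", "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["patient_id", "path", "label"])
        writer.writerows(rows)
    return out_dir


def load_dataset(in_dir: str | Path) -> list[CeusSample]:
    in_dir = Path(in_dir)
    samples = []
    with open(in_dir / "manifest.csv", newline="") as fh:
        for row in csv.DictReader(fh):
            pdir = in_dir / row["path"]
            meta = json.loads((pdir / "sample.json").read_text())
            frame_paths = sorted(pdir.glob("frame_*.png"))
            frames = np.stack([iio.imread(p) for p in frame_paths])
            samples.append(
                CeusSample(
                    patient_id=meta["patient_id"],
                    frames=frames,
                    keyframe_index=meta["keyframe_index"],
                    class_label=meta["class_label"],
                    clinical_attributes=meta["clinical_attributes"],
                )
            )
    return samples
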