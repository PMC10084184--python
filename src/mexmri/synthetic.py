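"""Synthetic data generators: phantoms, cohorts, and stain images.

Every input the analysis pipeline consumes can be generated here with
known ground truth, so the whole chain — forward signal model, noise,
fitting, map statistics, histology gating and group tests — is testable
end to end.

The phantom is a liver-like connected blob with per-voxel true (F, T1,
tau_exc) fields and an equilibrium magnetization M0 (arbitrary units).
Fibrotic presets add smooth high-F patches, emulating the spatial
variability of fibrosis severity; vessel voxels carry near-zero F and are
expected to fail the fit-quality gate. The forward signal includes an
imperfect-suppression baseline: with suppression fraction ``s`` the
longitudinal signal at delay t is

    M0 * [(1 - s) + s * recovery_fraction(params, t)]

i.e. residual magnetization (1 - s) survives the suppression block as an
additive constant. Magnitude noise is Rician by default (sigma = M0/SNR),
matching magnitude MRI reconstruction; Gaussian is available for
comparison. All generators are deterministic given an explicit seed; no
global random state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

from .fitting import ImageSeries
from .histology import ColorGate, rgb_to_ycbcr
from .model import MOUSE_SCHEDULE, RAT_SCHEDULE, AcquisitionSchedule

__all__ = [
    "Phantom",
    "NoiseModel",
    "CohortConfig",
    "load_preset",
    "PRESET_NAMES",
    "make_phantom",
    "simulate_series",
    "simulate_cohort",
    "make_stain_image",
]

PRESET_NAMES = ("rat_control", "rat_fibrosis", "mouse_control", "mouse_fibrosis")
_PHANTOM_PRESETS = ("homogeneous", "two_compartment") + PRESET_NAMES

SCHEDULES = {"rat": RAT_SCHEDULE, "mouse": MOUSE_SCHEDULE}


def load_preset(name: str) -> dict:
    """Load a named group preset (means/SDs, schedule, histology linkage)."""
    if name not in PRESET_NAMES:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    text = resources.files("mexmri.presets").joinpath(f"{name}.yaml").read_text()
    return yaml.safe_load(text)


@dataclass
class Phantom:
    """Ground-truth parameter fields on a liver-like ROI."""

    F_field: np.ndarray
    T1_field: np.ndarray
    tau_field: np.ndarray
    M0_field: np.ndarray
    roi: np.ndarray
    vessel_mask: np.ndarray

    def __post_init__(self) -> None:
        for name in ("F_field", "T1_field", "tau_field", "M0_field"):
            arr = getattr(self, name)
            if not np.all(np.isfinite(arr[self.roi])):
                raise ValueError(f"{name} is not finite inside the ROI")
        if np.any(self.F_field[self.vessel_mask] > 0.005):
            raise ValueError("vessel voxels must have F <= 0.005")


@dataclass(frozen=True)
class NoiseModel:
    """Acquisition imperfections: SNR, residual suppression, noise law."""

    snr: float = np.inf
    suppression: float = 1.0
    seed: int = 0
    distribution: str = "rician"

    def __post_init__(self) -> None:
        if not self.snr > 0:
            raise ValueError("snr must be positive (may be inf)")
        if not 0.0 <= self.suppression <= 1.0:
            raise ValueError("suppression fraction must lie in [0, 1]")
        if self.distribution not in ("rician", "gaussian"):
            raise ValueError("distribution must be 'rician' or 'gaussian'")


def _ellipse_roi(shape: tuple[int, int, int]) -> np.ndarray:
    """Connected, roughly liver-shaped blob: an ellipse filling ~55% of FOV."""
    nr, nc, ns = shape
    r, c = np.mgrid[0:nr, 0:nc]
    rc, cc = (nr - 1) / 2.0, (nc - 1) / 2.0
    mask2d = ((r - rc) / (0.42 * nr)) ** 2 + ((c - cc) / (0.42 * nc)) ** 2 <= 1.0
    return np.repeat(mask2d[:, :, None], ns, axis=2)


def _smooth_field(rng: np.random.Generator, shape, scale: float) -> np.ndarray:
    """Smooth zero-mean random field built from low-order cosine modes."""
    nr, nc, ns = shape
    r = np.linspace(0, np.pi, nr)[:, None, None]
    c = np.linspace(0, np.pi, nc)[None, :, None]
    out = np.zeros(shape)
    for kr in range(1, 4):
        for kc in range(1, 4):
            out += rng.normal() * np.cos(kr * r) * np.cos(kc * c)
    out -= out.mean()
    m = np.max(np.abs(out))
    return scale * out / m if m > 0 else out


def make_phantom(
    preset: str,
    size: tuple[int, int] | tuple[int, int, int] = (32, 32, 1),
    seed: int = 0,
    F: float | None = None,
    T1: float | None = None,
    tau: float | None = None,
    M0: float = 100.0,
) -> Phantom:
    """Build a ground-truth phantom.

    Presets: ``homogeneous`` (constant parameters in the ROI, no vessels),
    ``two_compartment`` (left/right halves at F = 0.05 / 0.15), and the
    four group presets (``rat_control`` ...), which use the group-mean
    parameters, add smooth high-F patches for fibrosis groups, and carve
    out low-F vessels. Explicit ``F``/``T1``/``tau`` override preset means.
    Deterministic given ``seed``.
    """
    if preset not in _PHANTOM_PRESETS:
        raise ValueError(f"unknown phantom preset {preset!r}")
    if len(size) == 2:
        size = (size[0], size[1], 1)
    if size[0] < 16 or size[1] < 16:
        raise ValueError("phantom must be at least 16x16 in-plane")

    rng = np.random.default_rng(seed)
    roi = _ellipse_roi(size)
    vessel = np.zeros(size, dtype=bool)

    if preset in PRESET_NAMES:
        cfg = load_preset(preset)
        base_F = F if F is not None else cfg["F"]["mean"]
        base_T1 = T1 if T1 is not None else cfg["T1_ms"]["mean"]
        base_tau = tau if tau is not None else cfg["tau_ms"]["mean"]
        fibrotic = cfg["group"] == "fibrosis"
    else:
        base_F = F if F is not None else 0.08
        base_T1 = T1 if T1 is not None else 1500.0
        base_tau = tau if tau is not None else 20.0
        fibrotic = False

    F_field = np.full(size, base_F)
    if preset == "two_compartment":
        half = size[1] // 2
        F_field[:, :half, :] = 0.05
        F_field[:, half:, :] = 0.15
    elif fibrotic:
        # smooth heterogeneity recentred so the ROI mean stays at base_F
        patches = _smooth_field(rng, size, scale=0.03)
        F_field = F_field + patches - patches[roi].mean()
        F_field = np.clip(F_field, 0.006, 0.5)
        shift = base_F - F_field[roi].mean()
        F_field = np.clip(F_field + shift, 0.006, 0.5)

    if preset in PRESET_NAMES:
        # a few small circular vessels inside the ROI
        nr, nc, _ = size
        r, c = np.mgrid[0:nr, 0:nc]
        for _ in range(3):
            vr = rng.uniform(0.35 * nr, 0.65 * nr)
            vc = rng.uniform(0.35 * nc, 0.65 * nc)
            rad = max(1.5, 0.04 * min(nr, nc))
            circ = (r - vr) ** 2 + (c - vc) ** 2 <= rad**2
            vessel |= circ[:, :, None] & roi
        F_field[vessel] = 0.002

    T1_field = np.full(size, base_T1)
    tau_field = np.full(size, base_tau)
    M0_field = np.where(roi, M0, 0.0)
    return Phantom(
        F_field=F_field, T1_field=T1_field, tau_field=tau_field,
        M0_field=M0_field, roi=roi, vessel_mask=vessel,
    )


def simulate_series(
    phantom: Phantom,
    schedule: AcquisitionSchedule,
    noise: NoiseModel = NoiseModel(),
) -> ImageSeries:
    """Forward-simulate a 4D magnitude series from a phantom.

    With full suppression (s = 1) and infinite SNR the normalized voxel
    curves equal the normalized recovery model exactly.
    """
    t = schedule.as_array()
    s = noise.suppression
    shape = phantom.roi.shape

    rf = (
        phantom.F_field[..., None]
        * (1.0 - np.exp(-t / phantom.tau_field[..., None]))
        + (1.0 - phantom.F_field[..., None])
        * (1.0 - np.exp(-t / phantom.T1_field[..., None]))
    )
    signal = phantom.M0_field[..., None] * ((1.0 - s) + s * rf)

    if np.isfinite(noise.snr):
        rng = np.random.default_rng(noise.seed)
        m0_ref = phantom.M0_field[phantom.roi].mean()
        sigma = m0_ref / noise.snr
        if noise.distribution == "rician":
            n1 = rng.normal(0.0, sigma, signal.shape)
            n2 = rng.normal(0.0, sigma, signal.shape)
            signal = np.sqrt((signal + n1) ** 2 + n2**2)
        else:
            signal = np.abs(signal + rng.normal(0.0, sigma, signal.shape))

    return ImageSeries(data=signal, schedule=schedule, roi=phantom.roi.copy())


@dataclass
class CohortConfig:
    """Two-group study design drawn from named presets.

    Per-animal ROI-mean true F and T1 are drawn from truncated normals at
    the preset group means/SDs; quantitative histology is linked linearly,
    histology% = slope * F_true + intercept + eps (clipped at 0), so the
    regression of histology on F does not pass through the origin.
    """

    control_preset: str = "rat_control"
    fibrosis_preset: str = "rat_fibrosis"
    n_control: int = 3
    n_fibrosis: int = 4
    size: tuple[int, int, int] = (16, 16, 1)
    snr: float = np.inf
    suppression: float = 1.0
    timepoint_weeks: int = 6
    linkage_noise_sd: float | None = None  # None -> preset value
    sd_scale: float = 1.0  # scales the preset between-animal SDs (0 -> exact means)


def simulate_cohort(
    config: CohortConfig, seed: int = 0
) -> tuple[dict[str, ImageSeries], "pd.DataFrame"]:
    """Simulate a two-group cohort with ground truth.

    Returns per-animal image series and a truth table (one row per animal)
    with true F/T1, linked histology percentage and inflammation score,
    ready for the fitting pipeline and group statistics.
    """
    import pandas as pd
    from scipy.stats import truncnorm

    if config.n_control < 2 or config.n_fibrosis < 2:
        raise ValueError("need at least 2 animals per group")

    rng = np.random.default_rng(seed)
    rows = []
    series: dict[str, ImageSeries] = {}
    for preset_name, n in (
        (config.control_preset, config.n_control),
        (config.fibrosis_preset, config.n_fibrosis),
    ):
        cfg = load_preset(preset_name)
        schedule = SCHEDULES[cfg["schedule"]]
        eps_sd = (
            config.linkage_noise_sd
            if config.linkage_noise_sd is not None
            else cfg["histology"]["noise_sd"]
        )
        for i in range(n):
            f_mu = cfg["F"]["mean"]
            f_sd = cfg["F"]["sd"] * config.sd_scale
            t1_mu = cfg["T1_ms"]["mean"]
            t1_sd = cfg["T1_ms"]["sd"] * config.sd_scale
            F_true = (
                f_mu if f_sd == 0 else float(
                    truncnorm.rvs(
                        (0.005 - f_mu) / f_sd, (0.5 - f_mu) / f_sd,
                        loc=f_mu, scale=f_sd, random_state=rng,
                    )
                )
            )
            T1_true = (
                t1_mu if t1_sd == 0 else float(
                    truncnorm.rvs(
                        (200.0 - t1_mu) / t1_sd, (4500.0 - t1_mu) / t1_sd,
                        loc=t1_mu, scale=t1_sd, random_state=rng,
                    )
                )
            )
            animal_id = f"{preset_name}_{i:02d}"
            phantom = make_phantom(
                "homogeneous", size=config.size,
                seed=int(rng.integers(2**31)),
                F=F_true, T1=T1_true, tau=cfg["tau_ms"]["mean"],
            )
            noise = NoiseModel(
                snr=config.snr, suppression=config.suppression,
                seed=int(rng.integers(2**31)),
            )
            series[animal_id] = simulate_series(phantom, schedule, noise)
            hist = cfg["histology"]
            histology_pct = max(
                0.0,
                hist["slope"] * F_true + hist["intercept"]
                + (rng.normal(0.0, eps_sd) if eps_sd > 0 else 0.0),
            )
            scores = cfg["inflammation_scores"]
            rows.append({
                "animal_id": animal_id,
                "group": cfg["group"],
                "timepoint_weeks": config.timepoint_weeks,
                "F_true": F_true,
                "T1_true_ms": T1_true,
                "histology_percent": histology_pct,
                "inflammation_score": int(rng.choice(scores)),
            })
    return series, pd.DataFrame(rows)


def _gate_candidate_colors(
    gate: ColorGate, inside: bool, step: int = 8
) -> np.ndarray:
    """RGB colors verified (via the studio-swing conversion) in/out of gate."""
    v = np.arange(0, 256, step, dtype=np.uint8)
    rr, gg, bb = np.meshgrid(v, v, v, indexing="ij")
    colors = np.stack([rr, gg, bb], axis=-1).reshape(-1, 1, 3)
    ycc = rgb_to_ycbcr(colors).astype(np.int16)
    in_gate = gate.contains(ycc).ravel()
    sel = colors.reshape(-1, 3)[in_gate if inside else ~in_gate]
    return sel


def make_stain_image(
    gate: ColorGate,
    target_fraction: float,
    size: tuple[int, int] = (100, 100),
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Build an RGB image with an exact in-gate pixel fraction.

    Exactly ``round(target_fraction * n_pixels)`` pixels take colors
    verified to fall inside the gate; all others take verified out-of-gate
    colors. Returns the uint8 image and the boolean truth mask.
    Deterministic given ``seed``.
    """
    if not 0.0 <= target_fraction <= 1.0:
        raise ValueError("target_fraction must lie in [0, 1]")
    in_colors = _gate_candidate_colors(gate, inside=True)
    if in_colors.shape[0] == 0:
        raise ValueError("gate admits no representable RGB color")
    out_colors = _gate_candidate_colors(gate, inside=False)
    if out_colors.shape[0] == 0:
        raise ValueError("gate covers the whole RGB cube; no background color")

    rng = np.random.default_rng(seed)
    n_pix = size[0] * size[1]
    n_in = int(round(target_fraction * n_pix))
    flat = np.empty((n_pix, 3), dtype=np.uint8)
    flat[:n_in] = in_colors[rng.integers(0, in_colors.shape[0], n_in)]
    flat[n_in:] = out_colors[rng.integers(0, out_colors.shape[0], n_pix - n_in)]
    order = rng.permutation(n_pix)
    image = flat[order].reshape(size[0], size[1], 3)
    truth = np.zeros(n_pix, dtype=bool)
    truth[:n_in] = True
    return image, truth[order].reshape(size[0], size[1])
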