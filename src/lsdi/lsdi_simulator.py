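"""Forward model of local-saturation-and-delay (LSDI) acquisition.

LSDI is a three-step MR scheme for imaging flow: (1) saturate a slab of
thickness ``sat_thickness`` perpendicular to the vessel, nulling its
longitudinal magnetization; (2) wait ``T_delay``; (3) read out with a
T1-weighted FLASH sequence.  Blood that flowed into the slab during the
flow-sensitive window ``tau = T_delay + TE`` carries fresh (unsaturated)
magnetization, so the upstream edge of the dark slab "sinks inward" by a
depth ``v(r) * tau`` at each radial position r — the image encodes the
radial velocity profile directly.

The renderer here models exactly the geometry the recovery pipeline relies
on: per excitation at cardiac phase ``phi``, an in-lumen pixel at radius r
and depth z into the slab is at full signal if ``z < v(r) * g(phi) * tau``
(fresh inflow, with ``g`` the systolic amplitude factor), otherwise at the
mono-exponential recovery level ``1 - exp(-tau / T1_blood)``.  The final
image averages over ``n_phase * n_averages`` excitations whose cardiac
phases advance deterministically by ``TR / T_C`` per excitation.  Bloch
simulation, k-space sampling and flow-related phase dispersion are out of
scope; flip-angle and steady-state effects are folded into the overall
signal normalization (full signal = 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import tifffile
import yaml

from .two_phase_flow import VelocityProfile

#: Default cardiac cycle length, ms (~375 bpm, typical anesthetized rat).
DEFAULT_T_C_MS = 160.0

#: Longitudinal relaxation time of arterial blood at 7 T, ms.
DEFAULT_T1_BLOOD_MS = 2200.0

TAU_BAND_MS = (10.0, 20.0)  # validity band of the flow-sensitive window
T_DELAY_BAND_MS = (8.0, 18.0)  # recommended delay band for rats


class ProtocolWarning(UserWarning):
    """Acquisition parameter outside its recommended band."""


class WindowExceedsDiastoleError(ValueError):
    """Flow-sensitive window tau longer than the diastolic interval."""


# ---------------------------------------------------------------------------
# Acquisition parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionProtocol:
    """LSDI acquisition parameters; defaults are a rat carotid protocol.

    Times in ms, fields of view in mm.  ``sat_thickness`` is the saturated
    slab thickness along the read (flow) axis.
    """

    TR: float = 100.0
    TE: float = 2.428
    T_delay: float = 17.572
    flip_angle: float = 40.0
    fov_read: float = 20.0
    fov_phase: float = 14.0
    n_read: int = 128
    n_phase: int = 96
    sat_thickness: float = 5.0
    n_averages: int = 20
    T1_blood: float = DEFAULT_T1_BLOOD_MS

    def __post_init__(self) -> None:
        for name in (
            "TR", "TE", "T_delay", "flip_angle", "fov_read", "fov_phase",
            "n_read", "n_phase", "sat_thickness", "n_averages", "T1_blood",
        ):
            val = getattr(self, name)
            if name == "T_delay":
                if val < 0:
                    raise ValueError("T_delay must be non-negative")
            elif not val > 0:
                raise ValueError(f"{name} must be positive, got {val}")
        lo, hi = T_DELAY_BAND_MS
        if not lo <= self.T_delay <= hi:
            warnings.warn(
                f"T_delay = {self.T_delay} ms outside the recommended "
                f"{lo}-{hi} ms band",
                ProtocolWarning,
                stacklevel=2,
            )


@dataclass(frozen=True)
class CardiacCycle:
    """Two-level (diastole/systole) cardiac waveform.

    ``T_C`` is the cycle length in ms (no default: it must always be given
    explicitly).  Diastole occupies the phase interval [0, diastolic_fraction);
    during systole the whole velocity profile is multiplied by
    ``systolic_gain``.
    """

    T_C: float
    diastolic_fraction: float = 0.6
    systolic_gain: float = 2.0
    phase0: float = 0.0

    def __post_init__(self) -> None:
        if not self.T_C > 0:
            raise ValueError("T_C must be positive")
        if not 0 < self.diastolic_fraction < 1:
            raise ValueError("diastolic_fraction must be in (0, 1)")
        if self.systolic_gain < 1:
            raise ValueError("systolic_gain must be >= 1")
        if not 0 <= self.phase0 < 1:
            raise ValueError("phase0 must be in [0, 1)")

    @property
    def T_dia(self) -> float:
        """Diastole length, ms."""
        return self.diastolic_fraction * self.T_C

    def is_diastole(self, phase) -> np.ndarray:
        return np.asarray(phase) < self.diastolic_fraction


@dataclass
class LSDIImage:
    """2-D LSDI intensity raster plus the geometry needed to interpret it.

    Rows run along the phase (radial) direction, columns along the read
    (flow) direction; intensities are in [0, 1] before noise with full
    (unsaturated) blood signal = 1.  ``sat_start``/``sat_end`` give the
    saturated-slab extent in read coordinates (mm); pixel centers sit at
    ``(index + 0.5) * spacing``.
    """

    intensities: np.ndarray
    spacing_read: float
    spacing_phase: float
    sat_start: float
    sat_end: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 2:
            raise ValueError("intensities must be a 2-D array")

    @property
    def read_coords(self) -> np.ndarray:
        """Column-center read coordinates, mm."""
        n = self.intensities.shape[1]
        return (np.arange(n) + 0.5) * self.spacing_read

    @property
    def phase_coords(self) -> np.ndarray:
        """Row-center phase coordinates, mm."""
        n = self.intensities.shape[0]
        return (np.arange(n) + 0.5) * self.spacing_phase

    @property
    def sat_thickness(self) -> float:
        return self.sat_end - self.sat_start


# ---------------------------------------------------------------------------
# Protocol-derived quantities
# ---------------------------------------------------------------------------

def pixel_spacing(protocol: AcquisitionProtocol) -> tuple[float, float]:
    """(read, phase) pixel spacing in mm: FOV / matrix per axis."""
    return (
        protocol.fov_read / protocol.n_read,
        protocol.fov_phase / protocol.n_phase,
    )


def scan_duration(protocol: AcquisitionProtocol) -> float:
    """Total scan time in seconds: TR * n_phase * n_averages (single slice)."""
    return protocol.TR * 1e-3 * protocol.n_phase * protocol.n_averages


def flow_sensitive_window(protocol: AcquisitionProtocol) -> float:
    """tau = T_delay + TE, ms; warns when outside the 10-20 ms validity band."""
    tau = protocol.T_delay + protocol.TE
    lo, hi = TAU_BAND_MS
    if not lo <= tau <= hi:
        warnings.warn(
            f"flow-sensitive window tau = {tau:.3f} ms outside [{lo}, {hi}] ms",
            ProtocolWarning,
            stacklevel=2,
        )
    return tau


def segmentation_threshold(
    protocol: AcquisitionProtocol, cycle: CardiacCycle, safety: float = 0.8
) -> float:
    """Intensity threshold separating diastolic from systole-only inflow.

    With excitations landing at effectively uniform cardiac phases, the
    probability that the flow-sensitive window is *not* fully contained in
    diastole is ``P = 1 - (T_dia - tau) / T_C``.  Pixels reached only by
    systolic inflow average an intensity of about P, while the diastolic
    tongue stays at full signal, so P separates the two.  The practical
    threshold is ``safety * P`` (default 80%) so that weak near-wall
    diastolic signal is not clipped.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ProtocolWarning)
        tau = flow_sensitive_window(protocol)
    t_dia = cycle.T_dia
    if t_dia < tau:
        raise WindowExceedsDiastoleError(
            f"diastole ({t_dia} ms) shorter than the flow-sensitive window "
            f"({tau} ms): threshold undefined"
        )
    p = 1.0 - (t_dia - tau) / cycle.T_C
    return safety * p


def sample_cardiac_phase(
    cycle: CardiacCycle, protocol: AcquisitionProtocol, n_excitations: int
) -> np.ndarray:
    """Cardiac phase of each excitation: ``(phase0 + k TR / T_C) mod 1``."""
    if n_excitations < 1:
        raise ValueError("n_excitations must be >= 1")
    k = np.arange(n_excitations)
    return (cycle.phase0 + k * protocol.TR / cycle.T_C) % 1.0


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_lsdi_image(
    profile: VelocityProfile,
    protocol: AcquisitionProtocol,
    cycle: CardiacCycle,
    noise_sigma: float = 0.0,
    seed: int = 0,
    *,
    vessel_center_phase: float | None = None,
    sat_start: float | None = None,
    tissue_level: float = 0.05,
    noise_model: str = "gaussian",
    n_excitations: int | None = None,
) -> LSDIImage:
    """Render a synthetic LSDI image of ``profile``.

    Parameters
    ----------
    profile : VelocityProfile
        Diastolic radial velocity profile (mm/s).
    noise_sigma : float
        Noise scale as a fraction of full signal, added once to the
        excitation-averaged image.  ``noise_model`` is ``"gaussian"``
        (default) or ``"rician"`` (magnitude of a complex signal with
        i.i.d. Gaussian components).
    vessel_center_phase : float, optional
        Vessel axis position along the phase direction, mm.  Defaults to
        mid-FOV plus a generic sub-pixel offset (0.3 pixel): a vessel
        aligned with the pixel raster is a degenerate configuration in
        which mirrored rows sample identical edge-quantization phases,
        halving the independent radial information.
    sat_start : float, optional
        Upstream edge of the saturated slab in read coordinates, mm.
        Defaults to centering the slab in the read FOV.
    """
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be non-negative")
    if noise_model not in ("gaussian", "rician"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    sp_read, sp_phase = pixel_spacing(protocol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ProtocolWarning)
        tau = flow_sensitive_window(protocol)

    geom = profile.geometry
    if 2 * geom.r_vessel > protocol.fov_phase:
        raise ValueError("vessel diameter exceeds the phase field of view")
    if vessel_center_phase is None:
        # generic position, deliberately not aligned with the pixel raster
        vessel_center_phase = (
            round(protocol.fov_phase / 2 / sp_phase) + 0.3
        ) * sp_phase
    if sat_start is None:
        sat_start = (protocol.fov_read - protocol.sat_thickness) / 2.0
    sat_end = sat_start + protocol.sat_thickness

    max_disp = profile.v_max * cycle.systolic_gain * tau * 1e-3
    if max_disp > protocol.sat_thickness:
        warnings.warn(
            f"peak systolic displacement {max_disp:.2f} mm exceeds the "
            f"saturated slab thickness {protocol.sat_thickness} mm: flow "
            "crosses the slab entirely",
            ProtocolWarning,
            stacklevel=2,
        )

    z = (np.arange(protocol.n_read) + 0.5) * sp_read
    y = (np.arange(protocol.n_phase) + 0.5) * sp_phase
    r = np.abs(y - vessel_center_phase)
    in_lumen = r < geom.r_vessel
    v_row = np.where(in_lumen, profile.velocity_at(np.minimum(r, geom.r_vessel)), 0.0)

    if n_excitations is None:
        n_excitations = protocol.n_phase * protocol.n_averages
    phases = sample_cardiac_phase(cycle, protocol, n_excitations)
    gains = np.where(cycle.is_diastole(phases), 1.0, cycle.systolic_gain)
    uniq_gains, counts = np.unique(gains, return_counts=True)
    weights = counts / counts.sum()

    recovery = 1.0 - np.exp(-tau / protocol.T1_blood)
    in_slice = (z >= sat_start) & (z < sat_end)
    depth = z - sat_start  # mm into the slab

    img = np.full((protocol.n_phase, protocol.n_read), tissue_level)
    lumen_mask = in_lumen[:, None] & np.ones_like(z, dtype=bool)[None, :]
    img[lumen_mask] = 1.0  # unsaturated blood up- and downstream
    for g, w in zip(uniq_gains, weights):
        reach = v_row[:, None] * g * tau * 1e-3  # mm
        bright = depth[None, :] < reach
        sig = np.where(bright, 1.0, recovery)
        region = in_lumen[:, None] & in_slice[None, :]
        if g == uniq_gains[0]:
            img[region] = 0.0
        img[region] += w * sig[region]

    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        if noise_model == "gaussian":
            img = img + rng.normal(0.0, noise_sigma, img.shape)
        else:
            n1 = rng.normal(0.0, noise_sigma, img.shape)
            n2 = rng.normal(0.0, noise_sigma, img.shape)
            img = np.sqrt((img + n1) ** 2 + n2**2)
        img = np.clip(img, 0.0, None)

    metadata = {
        "protocol": asdict(protocol),
        "cycle": asdict(cycle),
        "seed": int(seed),
        "noise_sigma": float(noise_sigma),
        "noise_model": noise_model,
        "tau_ms": float(tau),
        "vessel": {
            "r_vessel_mm": geom.r_vessel,
            "lambda_core": geom.lambda_core,
            "center_phase_mm": float(vessel_center_phase),
        },
        "sat_start_mm": float(sat_start),
        "sat_end_mm": float(sat_end),
    }
    return LSDIImage(
        intensities=img,
        spacing_read=sp_read,
        spacing_phase=sp_phase,
        sat_start=float(sat_start),
        sat_end=float(sat_end),
        metadata=metadata,
    )


# ---------------------------------------------------------------------------
# TIFF + YAML sidecar I/O
# ---------------------------------------------------------------------------

#: Full-scale value used when quantizing intensities to 16-bit TIFF.
TIFF_SCALE = 65535.0
#: Intensity mapped to TIFF full scale (leaves headroom for noise overshoot).
TIFF_MAX_INTENSITY = 2.0


def write_image(image: LSDIImage, tiff_path, meta_path=None) -> None:
    """Write a 16-bit grayscale TIFF and a YAML metadata sidecar."""
    scaled = np.clip(image.intensities / TIFF_MAX_INTENSITY, 0.0, 1.0)
    tifffile.imwrite(str(tiff_path), np.round(scaled * TIFF_SCALE).astype(np.uint16))
    if meta_path is None:
        meta_path = str(tiff_path) + ".yaml"
    sidecar = {
        "spacing_read_mm": image.spacing_read,
        "spacing_phase_mm": image.spacing_phase,
        "sat_start_mm": image.sat_start,
        "sat_end_mm": image.sat_end,
        "intensity_full_scale": TIFF_MAX_INTENSITY,
        "metadata": image.metadata,
    }
    with open(meta_path, "w") as fh:
        yaml.safe_dump(sidecar, fh, sort_keys=False)


def read_image(tiff_path, meta_path=None) -> LSDIImage:
    """Read an image written by :func:`write_image`."""
    if meta_path is None:
        meta_path = str(tiff_path) + ".yaml"
    with open(meta_path) as fh:
        sidecar = yaml.safe_load(fh)
    raw = tifffile.imread(str(tiff_path)).astype(float)
    full = sidecar.get("intensity_full_scale", 1.0)
    return LSDIImage(
        intensities=raw / TIFF_SCALE * full,
        spacing_read=sidecar["spacing_read_mm"],
        spacing_phase=sidecar["spacing_phase_mm"],
        sat_start=sidecar["sat_start_mm"],
        sat_end=sidecar["sat_end_mm"],
        metadata=sidecar.get("metadata", {}),
    )
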