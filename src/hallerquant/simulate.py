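"""Synthetic en face scenes and per-eye metric cohorts.

Two generators make every downstream stage testable without patient data:

* :func:`generate_vessel_image` draws dark vessel trunks as width-``w``
  random walks on a bright background, split into superior and inferior
  hemifields.  Each trunk's base orientation is sampled either from its
  hemifield's natural-oblique band (probability ``symmetry_fraction``) or
  from the mirrored non-natural band, so the ground-truth symmetry fraction
  is a generator dial.  The exact pre-noise mask and the per-trunk table are
  returned as oracles.

* :func:`generate_cohort` samples per-eye metric tables whose group means,
  SDs and diameter–CCT rank correlations emulate a published CSC / fellow /
  control cohort.  Marginals are truncated normals coupled by a Gaussian
  copula; mean vessel diameter is *derived* as area / length, and the latent
  area–CCT correlation is calibrated so the derived diameter attains the
  requested Spearman correlation with CCT.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from skimage.draw import disk as _disk

from .enface import EnFaceImage, EnFaceError, PIXEL_SIZE_MM_DEFAULT, VesselMask
from .symmetry import INFERIOR, SUPERIOR


class InfeasibleCorrelationError(EnFaceError):
    """Requested rank-correlation target cannot be realized."""


# ---------------------------------------------------------------------------
# vessel-scene generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VesselSceneParams:
    """Knobs of the synthetic en face scene.

    Defaults emulate the published scan geometry (7 x 7 mm at 512 x 512 px)
    and a Haller-layer-like vessel load: ~16 trunks per hemifield of mean
    width 11 px (~0.15 mm) give a vessel area near half the field and a
    skeleton length near 150 mm, the scale reported for real eyes.
    ``symmetry_fraction`` is the probability that a trunk is drawn in its
    hemifield's natural-oblique orientation band.
    """

    image_size_px: int = 512
    pixel_size_mm: float = PIXEL_SIZE_MM_DEFAULT
    n_trunks_per_hemifield: int = 16
    vessel_width_px_mean: float = 11.0
    vessel_width_px_sd: float = 2.0
    symmetry_fraction: float = 0.7
    tortuosity_deg: float = 6.0
    band_margin_deg: float = 15.0
    background_intensity: int = 200
    vessel_intensity: int = 60
    noise_sd: float = 20.0
    eye_side: str = "OD"
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.symmetry_fraction <= 1.0):
            raise EnFaceError("symmetry_fraction must lie in [0, 1]")
        if self.vessel_width_px_mean < 1:
            raise EnFaceError("vessel width must be >= 1 px")
        if self.vessel_width_px_mean >= self.image_size_px:
            raise EnFaceError("vessel width must be smaller than the image")
        for name in ("background_intensity", "vessel_intensity"):
            v = getattr(self, name)
            if not (0 <= v <= 255):
                raise EnFaceError(f"{name} must lie in [0, 255]")
        if self.vessel_intensity >= self.background_intensity:
            raise EnFaceError("vessels must be darker than the background")
        if self.eye_side not in ("OD", "OS"):
            raise EnFaceError("eye_side must be OD or OS")


def _walk_trunk(rng: np.random.Generator, start: Tuple[float, float],
                base_deg: float, tortuosity: float,
                row_lim: Tuple[float, float], n_cols: int,
                max_steps: int = 1200) -> np.ndarray:
    """Bidirectional unit-step walk; heading jitters around the base angle.

    Returns the path ordered end-to-end (backward arm reversed + start +
    forward arm), so ``path[0]`` and ``path[-1]`` are the trunk endpoints.
    """
    arms = []
    for sign in (1.0, -1.0):
        r, c = start
        jitter = 0.0
        arm = []
        for _ in range(max_steps):
            jitter = 0.85 * jitter + (rng.uniform(-tortuosity, tortuosity)
                                      if tortuosity > 0 else 0.0)
            ang = math.radians(base_deg + jitter)
            # anatomical angle: +x temporal (col), +y superior (decreasing row)
            c += sign * math.cos(ang)
            r -= sign * math.sin(ang)
            if not (row_lim[0] <= r <= row_lim[1]) or not (1 <= c <= n_cols - 2):
                break
            arm.append((r, c))
        arms.append(arm)
    pts = arms[1][::-1] + [start] + arms[0]
    return np.array(pts, dtype=float)


def generate_vessel_image(params: VesselSceneParams
                          ) -> Tuple[EnFaceImage, VesselMask, pd.DataFrame]:
    """Draw a synthetic slab image; return it with its ground-truth oracles.

    Returns the noisy grayscale :class:`EnFaceImage`, the exact pre-noise
    binary :class:`VesselMask`, and a per-trunk table (hemifield, base and
    realized endpoint orientations, natural flag, width, path pixel count).
    Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    n = params.image_size_px
    fovea_row = (n - 1) / 2.0
    mask = np.zeros((n, n), dtype=bool)
    rows = []
    lo, hi = params.band_margin_deg, 90.0 - params.band_margin_deg
    for hemifield in (SUPERIOR, INFERIOR):
        if hemifield == SUPERIOR:
            row_lim = (1.0, fovea_row - 2.0)
        else:
            row_lim = (fovea_row + 2.0, n - 2.0)
        # stratified natural/non-natural split so the realized natural-trunk
        # count is exactly round(s x n): the dial is the ground truth
        n_tr = params.n_trunks_per_hemifield
        n_nat = int(round(params.symmetry_fraction * n_tr))
        flags = np.array([True] * n_nat + [False] * (n_tr - n_nat))
        rng.shuffle(flags)
        for natural in map(bool, flags):
            mag = rng.uniform(lo, hi)
            # natural obliques rise temporally in the superior hemifield and
            # fall temporally in the inferior one; non-natural is the mirror
            if hemifield == SUPERIOR:
                base = mag if natural else -mag
            else:
                base = -mag if natural else mag
            width = max(1.0, rng.normal(params.vessel_width_px_mean,
                                        params.vessel_width_px_sd))
            start = (rng.uniform(row_lim[0] + 5, row_lim[1] - 5),
                     rng.uniform(0.08 * n, 0.92 * n))
            path = _walk_trunk(rng, start, base, params.tortuosity_deg, row_lim, n)
            radius = width / 2.0
            for r, c in path:
                rr, cc = _disk((r, c), radius, shape=mask.shape)
                mask[rr, cc] = True
            d_col = path[-1, 1] - path[0, 1]
            d_sup = path[0, 0] - path[-1, 0]
            realized = math.degrees(math.atan2(d_sup, d_col)) if len(path) > 1 else base
            if realized <= -90.0:
                realized += 180.0
            elif realized > 90.0:
                realized -= 180.0
            rows.append({
                "hemifield": hemifield,
                "natural": natural,
                "base_orientation_deg": base,
                "realized_orientation_deg": realized,
                "width_px": width,
                "n_path_px": len(path),
            })
    img = np.full((n, n), float(params.background_intensity))
    img[mask] = params.vessel_intensity
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    truth = pd.DataFrame(rows)
    if params.eye_side == "OS":  # scene is built in the OD (temporal=+x) frame
        img = np.fliplr(img)
        mask = np.fliplr(mask)
        truth["base_orientation_deg"] *= -1
        truth["realized_orientation_deg"] *= -1
    image = EnFaceImage(img, pixel_size_mm=params.pixel_size_mm,
                        eye_side=params.eye_side)
    return image, VesselMask(mask, params.pixel_size_mm), truth


# ---------------------------------------------------------------------------
# cohort generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupParams:
    """Marginal moments and CCT rank-correlation targets for one group."""

    name: str
    area_mean: float
    area_sd: float
    length_mean: float
    length_sd: float
    symmetry_mean: float
    symmetry_sd: float
    cct_mean: float
    cct_sd: float
    rho_diameter_cct: float = 0.0
    rho_symmetry_cct: float = 0.0
    rho_length_cct: float = 0.0
    n: int = 41

    def __post_init__(self) -> None:
        for name in ("area_sd", "length_sd", "symmetry_sd", "cct_sd"):
            if getattr(self, name) < 0:
                raise EnFaceError(f"{name} must be >= 0")
        for name in ("rho_diameter_cct", "rho_symmetry_cct", "rho_length_cct"):
            v = getattr(self, name)
            if not (-1.0 <= v <= 1.0):
                raise InfeasibleCorrelationError(f"{name}={v} outside [-1, 1]")
        if self.n < 3:
            raise EnFaceError("n per group must be >= 3")


@dataclass(frozen=True)
class CohortParams:
    groups: Tuple[GroupParams, ...]
    seed: int = 0


def default_cohort_params(n_per_group: int = 41, seed: int = 0) -> CohortParams:
    """Published-cohort defaults: group means ± SD and CCT couplings.

    Control / fellow / CSC vessel area (mm²), vessel length (mm), symmetry
    index (%) and CCT (µm) moments follow the reported tables; diameter–CCT
    Spearman targets follow the reported scatter correlations, and the
    negative control-group length–CCT coupling is included because without it
    the strong control diameter–CCT correlation is unattainable.
    """
    return CohortParams(groups=(
        GroupParams("control", 23.4, 3.3, 164.7, 24.5, 59.4, 5.8, 259, 87,
                    rho_diameter_cct=0.746, rho_symmetry_cct=0.0,
                    rho_length_cct=-0.364, n=n_per_group),
        GroupParams("fellow", 26.4, 4.8, 156.6, 20.5, 55.3, 7.2, 343, 100,
                    rho_diameter_cct=0.775, rho_symmetry_cct=-0.405,
                    rho_length_cct=0.0, n=n_per_group),
        GroupParams("csc", 27.4, 4.7, 150.0, 17.1, 53.7, 6.0, 391, 101,
                    rho_diameter_cct=0.745, rho_symmetry_cct=-0.660,
                    rho_length_cct=0.0, n=n_per_group),
    ), seed=seed)


def _trunc_normal_ppf(u: np.ndarray, mean: float, sd: float,
                      lo: float, hi: float) -> np.ndarray:
    if sd < 1e-8:
        return np.full_like(np.asarray(u, dtype=float), mean)
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.ppf(u, a, b, loc=mean, scale=sd)


def _spearman_to_pearson(rho: float) -> float:
    """Latent Gaussian correlation giving Spearman ``rho`` under a copula."""
    return 2.0 * math.sin(math.pi * rho / 6.0)


_CAL_CACHE: Dict[tuple, float] = {}
_N_CAL = 20_000


def _calibrate_area_cct(gp: GroupParams) -> float:
    """Latent area–CCT correlation so that area/length hits the diameter target.

    Solved by bisection on a fixed-seed latent sample; deterministic and
    cached per parameter set.  Raises when the target exceeds what the
    marginal spreads allow.
    """
    key = (round(gp.area_mean, 9), round(gp.area_sd, 9), round(gp.length_mean, 9),
           round(gp.length_sd, 9), round(gp.rho_diameter_cct, 9),
           round(gp.rho_length_cct, 9))
    if key in _CAL_CACHE:
        return _CAL_CACHE[key]
    if gp.area_sd < 1e-8 or gp.length_sd < 1e-8:
        _CAL_CACHE[key] = 0.0
        return 0.0
    rng = np.random.default_rng(987654321)
    z_c = rng.standard_normal(_N_CAL)
    e_a = rng.standard_normal(_N_CAL)
    e_l = rng.standard_normal(_N_CAL)
    r_lc = _spearman_to_pearson(gp.rho_length_cct)
    z_l = r_lc * z_c + math.sqrt(1.0 - r_lc ** 2) * e_l
    length = _trunc_normal_ppf(stats.norm.cdf(z_l), gp.length_mean, gp.length_sd,
                               0.0, np.inf)

    def derived_rho(r_ac: float) -> float:
        z_a = r_ac * z_c + math.sqrt(max(0.0, 1.0 - r_ac ** 2)) * e_a
        area = _trunc_normal_ppf(stats.norm.cdf(z_a), gp.area_mean, gp.area_sd,
                                 0.0, np.inf)
        return float(stats.spearmanr(area / length, z_c).statistic)

    target = gp.rho_diameter_cct
    lo_r, hi_r = -0.9999, 0.9999
    f_lo, f_hi = derived_rho(lo_r), derived_rho(hi_r)
    if not (f_lo - 0.02 <= target <= f_hi + 0.02):
        raise InfeasibleCorrelationError(
            f"group {gp.name!r}: diameter-CCT Spearman target {target:.3f} outside "
            f"achievable range [{f_lo:.3f}, {f_hi:.3f}] for the given marginals"
        )
    for _ in range(40):
        mid = 0.5 * (lo_r + hi_r)
        if derived_rho(mid) < target:
            lo_r = mid
        else:
            hi_r = mid
    r_ac = 0.5 * (lo_r + hi_r)
    _CAL_CACHE[key] = r_ac
    return r_ac


def generate_cohort(params: CohortParams) -> pd.DataFrame:
    """Sample a per-eye metric cohort table.

    Columns: eye_id, group, vessel_area_mm2, vessel_length_mm,
    mean_diameter_mm (= area/length, self-consistent), symmetry_index_pct,
    cct_um.  Reproducible for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    frames = []
    for gp in params.groups:
        r_ac = _calibrate_area_cct(gp)
        r_lc = _spearman_to_pearson(gp.rho_length_cct)
        r_sc = _spearman_to_pearson(gp.rho_symmetry_cct)
        z_c = rng.standard_normal(gp.n)
        z_a = r_ac * z_c + math.sqrt(max(0.0, 1.0 - r_ac ** 2)) * rng.standard_normal(gp.n)
        z_l = r_lc * z_c + math.sqrt(max(0.0, 1.0 - r_lc ** 2)) * rng.standard_normal(gp.n)
        z_s = r_sc * z_c + math.sqrt(max(0.0, 1.0 - r_sc ** 2)) * rng.standard_normal(gp.n)
        area = _trunc_normal_ppf(stats.norm.cdf(z_a), gp.area_mean, gp.area_sd, 0.0, np.inf)
        length = _trunc_normal_ppf(stats.norm.cdf(z_l), gp.length_mean, gp.length_sd, 0.0, np.inf)
        sym = _trunc_normal_ppf(stats.norm.cdf(z_s), gp.symmetry_mean, gp.symmetry_sd, 0.0, 100.0)
        cct = _trunc_normal_ppf(stats.norm.cdf(z_c), gp.cct_mean, gp.cct_sd, 0.0, np.inf)
        frames.append(pd.DataFrame({
            "eye_id": [f"{gp.name}-{i:04d}" for i in range(gp.n)],
            "group": gp.name,
            "vessel_area_mm2": area,
            "vessel_length_mm": length,
            "mean_diameter_mm": area / length,
            "symmetry_index_pct": sym,
            "cct_um": cct,
        }))
    return pd.concat(frames, ignore_index=True)
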