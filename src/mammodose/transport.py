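"""Vectorized Monte Carlo photon transport through paddle, phantom and
support, with per-compartment energy-deposition tallies.

Physics model (mammographic range, 1-28 keV):

* free-path sampling by delta (Woodcock) tracking against an
  energy-dependent majorant, so voxel boundaries never need ray tracing;
* photoelectric absorption deposits the full photon energy locally
  (kerma approximation -- photoelectron and recoil-electron ranges at
  these energies are well below the voxel pitch, and fluorescence
  yields in low-Z tissue are negligible);
* incoherent scattering samples the Klein-Nishina free-electron angular
  law by rejection and deposits the recoil energy locally; photons
  falling below 1 keV are absorbed on the spot;
* coherent scattering redirects without energy loss using the Thomson
  angular law (a deliberate form-factor-free simplification; it can be
  switched off entirely).

Batches use independent random subsequences derived from (seed, batch),
so results are bit-reproducible and batches are independent by
construction; batch scatter provides the relative-error estimate.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .materials import Material, builtin_materials, linear_attenuation
from .phantom import (ADIPOSE, AIR, GLANDULAR, INTERIOR_MIX, SKIN,
                      VoxelPhantom, dosimeter_positions)
from .spectrum import BeamConfig, EnergySpectrum

__all__ = [
    "TransportConfig", "TallyResult",
    "sample_source", "sample_compton", "sample_interaction",
    "run_transport", "relative_error",
    "COMPARTMENTS", "ENERGY_CUTOFF_KEV",
]

ENERGY_CUTOFF_KEV = 1.0
MEC2_KEV = 511.0
_MAX_STEPS = 10_000

#: tally compartments, indexed by region code
COMPARTMENTS = ("air", "skin", "glandular", "adipose", "interior",
                "paddle", "support")
_R_AIR, _R_SKIN, _R_GLAND, _R_ADIP, _R_MIX, _R_PADDLE, _R_SUPPORT = range(7)

POINT_TALLY_RADIUS_CM = 0.15


@dataclass(frozen=True)
class TransportConfig:
    """History count, batching and physics switches for one run."""

    histories: int = 1_000_000
    batches: int = 20
    seed: int = 0
    kerma_approximation: bool = True      # documented; always local deposit
    coherent: bool = True
    support_mm: float = 5.0               # polycarbonate support thickness

    def __post_init__(self):
        if self.batches < 2:
            raise ValueError("need at least 2 batches for statistics")
        if self.histories < self.batches:
            raise ValueError("histories must be >= batches")


@dataclass
class TallyResult:
    """Per-batch energy deposits (keV) per compartment and point tally."""

    batch_edep: np.ndarray          # (batches, n_compartments)
    point_edep: np.ndarray          # (batches, n_points)
    batch_source_kev: np.ndarray    # (batches,) emitted energy per batch
    histories: int
    seed: int
    livelock_terminations: int = 0
    point_positions: List[Tuple[float, float, float]] = field(
        default_factory=list)

    @property
    def compartment_totals(self) -> Dict[str, float]:
        tot = self.batch_edep.sum(axis=0)
        return {name: float(v) for name, v in zip(COMPARTMENTS, tot)}

    def to_json(self) -> str:
        return json.dumps({
            "histories": self.histories,
            "seed": self.seed,
            "compartments": list(COMPARTMENTS),
            "batch_edep_kev": self.batch_edep.tolist(),
            "point_edep_kev": self.point_edep.tolist(),
            "batch_source_kev": self.batch_source_kev.tolist(),
            "point_positions_cm": [list(p) for p in self.point_positions],
            "livelock_terminations": self.livelock_terminations,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "TallyResult":
        d = json.loads(text)
        return cls(np.array(d["batch_edep_kev"]),
                   np.array(d["point_edep_kev"]),
                   np.array(d["batch_source_kev"]),
                   d["histories"], d["seed"],
                   d["livelock_terminations"],
                   [tuple(p) for p in d["point_positions_cm"]])


def relative_error(tally: TallyResult) -> Dict[str, Optional[float]]:
    """Standard error of the batch means over the mean, per compartment.

    A zero-mean compartment reports ``None`` (undefined) rather than
    failing.
    """
    out: Dict[str, Optional[float]] = {}
    n = tally.batch_edep.shape[0]
    for i, name in enumerate(COMPARTMENTS):
        vals = tally.batch_edep[:, i]
        mean = vals.mean()
        if mean == 0:
            out[name] = None
            continue
        se = vals.std(ddof=1) / math.sqrt(n)
        out[name] = float(se / mean)
    return out


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def sample_source(spectrum: EnergySpectrum, beam: BeamConfig, count: int,
                  rng: np.random.Generator,
                  target_box: Tuple[Tuple[float, float], Tuple[float, float]]
                  = ((-8.0, 8.0), (0.0, 8.0)),
                  z_plane: float = 0.0,
                  ) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sample source photons: energies from the binned spectrum, origins
    at the focal spot above the chest-wall midpoint, directions toward
    uniform points on the field rectangle clipped to ``target_box`` at
    ``z_plane`` (the phantom's upper surface).

    Returns (positions, directions, energies); reproducible given rng.
    """
    if spectrum.total_fluence <= 0:
        raise ValueError("cannot sample from an empty spectrum")
    p = spectrum.fluence / spectrum.total_fluence
    idx = rng.choice(p.size, size=count, p=p)
    energies = spectrum.edges_kev[idx] + rng.random(count) * 0.1

    fx, fy = beam.field_cm
    (x0, x1), (y0, y1) = target_box
    x0, x1 = max(x0, -fx / 2), min(x1, fx / 2)
    y0, y1 = max(y0, 0.0), min(y1, fy)
    tx = rng.uniform(x0, x1, count)
    ty = rng.uniform(y0, y1, count)

    src = np.array([0.0, 0.0, z_plane + beam.source_breast_cm])
    pos = np.broadcast_to(src, (count, 3)).copy()
    d = np.stack([tx - src[0], ty - src[1],
                  np.full(count, z_plane - src[2])], axis=1)
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    return pos, d, energies


def sample_compton(energy_kev, rng: np.random.Generator):
    """Klein-Nishina scatter: returns (scattered energy keV, cos theta).

    Vectorized rejection sampling of the free-electron differential
    cross-section; the scattered energy follows the Compton relation.
    """
    e = np.atleast_1d(np.asarray(energy_kev, float))
    k = e / MEC2_KEV
    mu = np.empty_like(e)
    todo = np.ones(e.shape, bool)
    while todo.any():
        m = rng.uniform(-1.0, 1.0, int(todo.sum()))
        r = 1.0 / (1.0 + k[todo] * (1.0 - m))
        f = r * r * (r + 1.0 / r - (1.0 - m * m))
        acc = rng.random(m.size) * 2.0 < f       # f <= 2 on [-1, 1]
        sel = np.flatnonzero(todo)[acc]
        mu[sel] = m[acc]
        todo[sel] = False
    e_out = e / (1.0 + k * (1.0 - mu))
    if np.isscalar(energy_kev):
        return float(e_out[0]), float(mu[0])
    return e_out, mu


def _thomson_mu(count: int, rng: np.random.Generator) -> np.ndarray:
    """Cosine of the coherent-scatter angle from the Thomson law."""
    mu = np.empty(count)
    todo = np.ones(count, bool)
    while todo.any():
        m = rng.uniform(-1.0, 1.0, int(todo.sum()))
        acc = rng.random(m.size) * 2.0 < (1.0 + m * m)
        sel = np.flatnonzero(todo)[acc]
        mu[sel] = m[acc]
        todo[sel] = False
    return mu


def sample_interaction(material: Material, energy_kev, rng: np.random.Generator,
                       coherent: bool = True):
    """Draw the interaction channel with probability proportional to the
    partial mass attenuation coefficients.

    Returns "photoelectric" | "incoherent" | "coherent" (scalar energy)
    or an integer array coded 0/1/2.  With ``coherent=False`` the
    coherent channel is folded out and the rest renormalized.
    """
    from .materials import mass_attenuation
    e = np.atleast_1d(np.asarray(energy_kev, float))
    pe = mass_attenuation(material, e, "photoelectric")
    inc = mass_attenuation(material, e, "incoherent")
    coh = mass_attenuation(material, e, "coherent") if coherent else 0.0
    tot = pe + inc + coh
    u = rng.random(e.shape) * tot
    code = np.where(u < pe, 0, np.where(u < pe + inc, 1, 2))
    if np.isscalar(energy_kev):
        return ("photoelectric", "incoherent", "coherent")[int(code[0])]
    return code


def _rotate(directions: np.ndarray, mu: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vectors by polar angle acos(mu), uniform azimuth."""
    d = directions
    sin_t = np.sqrt(np.clip(1.0 - mu * mu, 0.0, None))
    phi = rng.uniform(0.0, 2.0 * np.pi, mu.size)
    # orthonormal frame (u, v, d); avoid degeneracy near the z axis
    near_z = np.abs(d[:, 2]) > 0.99
    a = np.where(near_z[:, None],
                 np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0]))
    u = np.cross(a, d)
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    v = np.cross(d, u)
    out = (mu[:, None] * d
           + (sin_t * np.cos(phi))[:, None] * u
           + (sin_t * np.sin(phi))[:, None] * v)
    out /= np.linalg.norm(out, axis=1, keepdims=True)
    return out


# ---------------------------------------------------------------------------
# Cross-section cache on a fine energy grid
# ---------------------------------------------------------------------------

_FINE_STEP_KEV = 0.02


class _XsecCache:
    """Linear attenuation and channel probabilities per region material,
    pre-tabulated on a fine energy grid for O(1) lookup."""

    def __init__(self, region_materials: Dict[int, Material], e_max: float,
                 coherent: bool):
        self.e_min = ENERGY_CUTOFF_KEV
        self.grid = np.arange(self.e_min, e_max + _FINE_STEP_KEV,
                              _FINE_STEP_KEV)
        n_reg = max(region_materials) + 1
        ng = self.grid.size
        self.mu = np.zeros((n_reg, ng))
        self.p_pe = np.zeros((n_reg, ng))
        self.p_inc = np.zeros((n_reg, ng))
        from .materials import mass_attenuation
        for code, mat in region_materials.items():
            pe = mass_attenuation(mat, self.grid, "photoelectric")
            inc = mass_attenuation(mat, self.grid, "incoherent")
            coh = (mass_attenuation(mat, self.grid, "coherent")
                   if coherent else np.zeros(ng))
            tot = pe + inc + coh
            self.mu[code] = tot * mat.density
            self.p_pe[code] = pe / tot
            self.p_inc[code] = inc / tot
        self.majorant = self.mu.max(axis=0)

    def index(self, energy: np.ndarray) -> np.ndarray:
        i = np.rint((energy - self.e_min) / _FINE_STEP_KEV).astype(np.intp)
        return np.clip(i, 0, self.grid.size - 1)


# ---------------------------------------------------------------------------
# Main transport driver
# ---------------------------------------------------------------------------

def _region_codes(pos: np.ndarray, phantom: VoxelPhantom,
                  z_paddle: Tuple[float, float],
                  z_support: Tuple[float, float]) -> np.ndarray:
    """Map positions to region codes (air/skin/.../paddle/support)."""
    z = pos[:, 2]
    codes = np.full(pos.shape[0], _R_AIR, dtype=np.int8)
    in_paddle = (z >= z_paddle[0]) & (z <= z_paddle[1])
    in_support = (z >= z_support[0]) & (z < z_support[1])
    codes[in_paddle] = _R_PADDLE
    codes[in_support] = _R_SUPPORT
    in_ph = (z >= 0.0) & (z < phantom.spec.thickness_cm) \
        & ~in_paddle & ~in_support
    if in_ph.any():
        h = phantom.voxel_mm / 10.0
        idx = np.flatnonzero(in_ph)
        i = ((pos[idx, 0] - phantom.origin_cm[0]) / h).astype(np.intp)
        j = ((pos[idx, 1] - phantom.origin_cm[1]) / h).astype(np.intp)
        kk = ((pos[idx, 2] - phantom.origin_cm[2]) / h).astype(np.intp)
        nx, ny, nz = phantom.shape
        np.clip(i, 0, nx - 1, out=i)
        np.clip(j, 0, ny - 1, out=j)
        np.clip(kk, 0, nz - 1, out=kk)
        lab = phantom.labels[i, j, kk]
        # phantom labels coincide with region codes 0..4 by construction
        codes[idx] = lab.astype(np.int8)
    return codes


def run_transport(phantom: VoxelPhantom, spectrum: EnergySpectrum,
                  beam: BeamConfig, config: TransportConfig,
                  point_positions: Optional[Sequence[Tuple[float, float, float]]]
                  = None) -> TallyResult:
    """Transport ``config.histories`` photons and tally energy deposits.

    Geometry: the compression paddle (``beam.paddle_mm`` polycarbonate)
    sits directly on the phantom's upper surface and the support plate
    (``config.support_mm``) directly below it; everything else inside
    the bounding box is air.  Photons start at the paddle's upper
    surface (the spectrum fed in should NOT already include the paddle,
    which is part of the tracked geometry here).
    """
    reg = builtin_materials()
    t = phantom.spec.thickness_cm
    z_paddle = (t, t + beam.paddle_mm / 10.0)
    z_support = (-config.support_mm / 10.0, 0.0)
    r = phantom.spec.footprint_radius_cm
    box_lo = np.array([-r, 0.0, z_support[0]])
    box_hi = np.array([r, r, z_paddle[1]])

    region_mats = {_R_AIR: reg["air"], _R_SKIN: reg["skin"],
                   _R_PADDLE: reg["polycarbonate"],
                   _R_SUPPORT: reg["polycarbonate"]}
    if phantom.spec.mode == "mixture":
        region_mats[_R_MIX] = phantom.materials[INTERIOR_MIX]
    else:
        region_mats[_R_GLAND] = phantom.materials[GLANDULAR]
        region_mats[_R_ADIP] = phantom.materials[ADIPOSE]

    cache = _XsecCache(region_mats, float(spectrum.edges_kev[-1]) + 0.1,
                       config.coherent)

    if point_positions is None and phantom.spec.mode == "non-mixture":
        try:
            point_positions = dosimeter_positions(phantom)
        except ValueError:
            point_positions = []
    pts = np.array(point_positions if point_positions else []).reshape(-1, 3)

    n_comp = len(COMPARTMENTS)
    batch_edep = np.zeros((config.batches, n_comp))
    point_edep = np.zeros((config.batches, max(len(pts), 1)))
    batch_src = np.zeros(config.batches)
    livelock = 0

    per_batch = config.histories // config.batches
    counts = [per_batch + (1 if b < config.histories % config.batches else 0)
              for b in range(config.batches)]

    for b in range(config.batches):
        rng = np.random.default_rng(np.random.SeedSequence((config.seed, b)))
        pos, dirs, energy = sample_source(
            spectrum, beam, counts[b], rng,
            target_box=((box_lo[0], box_hi[0]), (box_lo[1], box_hi[1])),
            z_plane=t)
        batch_src[b] = energy.sum()
        # advance analytically to the paddle top (vacuum above geometry)
        step_in = (z_paddle[1] - pos[:, 2]) / dirs[:, 2]
        pos = pos + dirs * step_in[:, None] * (1 + 1e-12)

        edep = np.zeros(n_comp)
        pdep = np.zeros(max(len(pts), 1))
        steps = np.zeros(pos.shape[0], dtype=np.int32)

        alive = np.ones(pos.shape[0], bool)
        while alive.any():
            ia = np.flatnonzero(alive)
            p = pos[ia]
            d = dirs[ia]
            e = energy[ia]
            ei = cache.index(e)
            mu_maj = cache.majorant[ei]
            flight = -np.log(rng.random(ia.size)) / mu_maj
            p = p + d * flight[:, None]
            pos[ia] = p

            steps[ia] += 1
            stuck = steps[ia] >= _MAX_STEPS
            out = ((p < box_lo) | (p > box_hi)).any(axis=1)
            gone = out | stuck
            if stuck.any():
                # deposit the photon's remaining energy where it stands
                codes_stuck = _region_codes(p[stuck], phantom, z_paddle,
                                            z_support)
                np.add.at(edep, codes_stuck, e[stuck])
                livelock += int(stuck.sum())
            if gone.any():
                alive[ia[gone]] = False
                keep = ~gone
                ia, p, d, e, ei, mu_maj = (ia[keep], p[keep], d[keep],
                                           e[keep], ei[keep], mu_maj[keep])
                if ia.size == 0:
                    continue

            codes = _region_codes(p, phantom, z_paddle, z_support)
            mu_here = cache.mu[codes, ei]
            real = rng.random(ia.size) < mu_here / mu_maj
            if not real.any():
                continue
            ir = ia[real]
            rp = p[real]
            re_ = e[real]
            rcodes = codes[real]
            rei = ei[real]

            u = rng.random(ir.size)
            p_pe = cache.p_pe[rcodes, rei]
            p_inc = cache.p_inc[rcodes, rei]
            is_pe = u < p_pe
            is_inc = ~is_pe & (u < p_pe + p_inc)
            is_coh = ~is_pe & ~is_inc

            deposit = np.zeros(ir.size)
            deposit[is_pe] = re_[is_pe]
            if is_inc.any():
                e_new, mu_sc = sample_compton(re_[is_inc], rng)
                deposit[is_inc] = re_[is_inc] - e_new
                below = e_new < ENERGY_CUTOFF_KEV
                deposit[np.flatnonzero(is_inc)[below]] += e_new[below]
                keep_idx = np.flatnonzero(is_inc)[~below]
                energy[ir[keep_idx]] = e_new[~below]
                dirs[ir[keep_idx]] = _rotate(dirs[ir[keep_idx]],
                                             mu_sc[~below], rng)
                dead_inc = np.flatnonzero(is_inc)[below]
                alive[ir[dead_inc]] = False
            if is_coh.any():
                mu_c = _thomson_mu(int(is_coh.sum()), rng)
                dirs[ir[is_coh]] = _rotate(dirs[ir[is_coh]], mu_c, rng)
            alive[ir[is_pe]] = False

            np.add.at(edep, rcodes, deposit)
            if len(pts) and deposit.any():
                dz = rp[:, None, :] - pts[None, :, :]
                inside = (dz ** 2).sum(axis=2) <= POINT_TALLY_RADIUS_CM ** 2
                pdep[:len(pts)] += (inside * deposit[:, None]).sum(axis=0)

        batch_edep[b] = edep
        point_edep[b] = pdep

    return TallyResult(batch_edep, point_edep, batch_src,
                       config.histories, config.seed, livelock,
                       [tuple(p) for p in pts])
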