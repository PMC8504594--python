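"""One-time generator for the packaged photon-interaction coefficient tables.

Writes one plain-text table per element to src/mammodose/data/coeff/.
Columns: energy (keV), photoelectric, incoherent, coherent, total,
mass energy-absorption (all cm^2/g).

Physics sources, all evaluated locally:
  * photoelectric  -- optical theorem on the Cromer-Liberman anomalous
    scattering factor f'' (gemmi implementation of the reference fits)
  * coherent       -- Thomson cross-section weighted by the squared IT92
    atomic form factor, Gauss-Legendre quadrature over angle
  * incoherent     -- Klein-Nishina weighted by the Waller-Hartree
    incoherent scattering function S(q,Z) ~ Z - f(q)^2/Z
  * energy absorption -- photoelectric with a fluorescence-escape
    correction (edge-jump branching x shell yield x mean line energy)
    plus the Klein-Nishina energy-transfer moment of the incoherent term

Run from the repository root:  python tools/make_coefficient_tables.py
"""

import numpy as np
import gemmi

R_E = 2.8179403262e-13      # classical electron radius, cm
HC_KEV_A = 12.39841984      # h*c in keV * Angstrom
N_A = 6.02214076e23
MEC2 = 511.0                # electron rest energy, keV

ELEMENTS = ["H", "Be", "C", "N", "O", "Na", "Mg", "Al", "Si", "P",
            "S", "Cl", "Ar", "K", "Ti", "Rh", "Ag", "W"]

# K-shell binding energies (keV) for elements whose edge falls in 1-50 keV,
# K fluorescence yields, and mean K-line energy as a fraction of the edge.
K_EDGE = {"Na": 1.0721, "Mg": 1.3050, "Al": 1.5596, "Si": 1.8389,
          "P": 2.1455, "S": 2.4720, "Cl": 2.8224, "Ar": 3.2029,
          "K": 3.6074, "Ti": 4.9664, "Rh": 23.2199, "Ag": 25.5140}
K_YIELD = {"Na": 0.023, "Mg": 0.030, "Al": 0.039, "Si": 0.050,
           "P": 0.063, "S": 0.078, "Cl": 0.097, "Ar": 0.118,
           "K": 0.140, "Ti": 0.214, "Rh": 0.808, "Ag": 0.830}
# W works through its L shell in this energy range.
W_L_EDGES = [10.2068, 11.5440, 12.0998]
W_L_YIELD = 0.25            # mean L-shell fluorescence yield
W_L_LINE = 8.9              # mean L-line energy, keV

NICE = [1.5, 2.0, 3.0, 4.0, 5.0, 6.0, 8.0, 8.397, 9.672, 10.0, 11.286,
        15.0, 20.0, 25.0, 28.0, 30.0, 40.0, 50.0]


def photoelectric(z, e_kev):
    lam_cm = HC_KEV_A / e_kev * 1e-8
    fpp = np.array([gemmi.cromer_liberman(z=z, energy=float(e) * 1e3)[1]
                    for e in np.atleast_1d(e_kev)])
    sigma = 2.0 * R_E * lam_cm * fpp      # cm^2/atom
    return sigma


def scatter_integrals(symbol, z, e_kev, n_quad=512):
    """Coherent / incoherent atomic cross sections and the incoherent
    energy-transfer cross section, by quadrature over scattering angle."""
    it92 = gemmi.Element(symbol).it92
    mu, w = np.polynomial.legendre.leggauss(n_quad)   # mu = cos(theta)
    lam_a = HC_KEV_A / e_kev                          # Angstrom
    # sin(theta/2)/lambda for each (energy, angle)
    s = np.sqrt(np.clip((1.0 - mu) / 2.0, 0, None))[None, :] / lam_a[:, None]
    f = np.array([[it92.calculate_sf(float(x * x)) for x in row] for row in s])
    thomson = 0.5 * R_E**2 * (1.0 + mu**2)[None, :]
    sig_coh = 2 * np.pi * np.sum(thomson * f**2 * w[None, :], axis=1)

    k = e_kev[:, None] / MEC2
    ratio = 1.0 / (1.0 + k * (1.0 - mu[None, :]))     # E'/E
    kn = 0.5 * R_E**2 * ratio**2 * (ratio + 1.0 / ratio - (1.0 - mu[None, :]**2))
    s_incoh = np.clip(z - f**2 / z, 0.0, z)
    sig_inc = 2 * np.pi * np.sum(kn * s_incoh * w[None, :], axis=1)
    sig_inc_tr = 2 * np.pi * np.sum(kn * s_incoh * (1.0 - ratio) * w[None, :], axis=1)
    return sig_coh, sig_inc, sig_inc_tr


def fluorescence_factor(symbol, z, e_kev):
    """Fraction of the photoelectric energy retained locally."""
    retained = np.ones_like(e_kev)
    def jump_fraction(edge):
        lo = photoelectric(z, np.array([edge * (1 - 5e-4)]))[0]
        hi = photoelectric(z, np.array([edge * (1 + 5e-4)]))[0]
        return max(0.0, 1.0 - lo / hi) if hi > 0 else 0.0
    if symbol in K_EDGE and K_EDGE[symbol] < 50.0:
        edge = K_EDGE[symbol]
        above = e_kev > edge
        p_k = jump_fraction(edge)
        e_line = 0.90 * edge
        retained[above] -= p_k * K_YIELD[symbol] * e_line / e_kev[above]
    if symbol == "W":
        for edge in W_L_EDGES:
            above = e_kev > edge
            p_l = jump_fraction(edge)
            retained[above] -= p_l * W_L_YIELD * W_L_LINE / e_kev[above]
    return np.clip(retained, 0.0, 1.0)


def energy_grid(symbol):
    grid = set(np.round(np.geomspace(1.0, 50.0, 60), 6))
    grid.update(NICE)
    edges = []
    if symbol in K_EDGE:
        edges.append(K_EDGE[symbol])
    if symbol == "W":
        edges.extend(W_L_EDGES)
    # L/M structure below the K edge for the heavier elements
    extra = {"Rh": [3.0043, 3.1461, 3.4119], "Ag": [3.3511, 3.5237, 3.8058],
             "W": [1.8092, 1.8716, 2.2810, 2.5749, 2.8196],
             "Ti": [], "K": [], "Ar": [], "Cl": []}
    edges.extend(extra.get(symbol, []))
    for e in edges:
        if 1.0 < e < 50.0:
            grid.discard(round(e, 6))
            grid.update([round(e * (1 - 5e-4), 6), round(e * (1 + 5e-4), 6)])
    return np.array(sorted(g for g in grid if 1.0 <= g <= 50.0))


def main():
    import pathlib
    out = pathlib.Path(__file__).resolve().parents[1] / "src/mammodose/data/coeff"
    out.mkdir(parents=True, exist_ok=True)
    for symbol in ELEMENTS:
        el = gemmi.Element(symbol)
        z, a = el.atomic_number, el.weight
        e = energy_grid(symbol)
        per_atom_to_mass = N_A / a
        # floor keeps log-log interpolation defined (H photoabsorption is
        # below the fit's resolution over part of the range)
        pe = np.maximum(photoelectric(z, e) * per_atom_to_mass, 1e-12)
        coh, inc, inc_tr = (x * per_atom_to_mass for x in scatter_integrals(symbol, z, e))
        total = pe + inc + coh
        muen = pe * fluorescence_factor(symbol, z, e) + inc_tr
        with open(out / f"{symbol}.txt", "w") as fh:
            fh.write(f"# Photon mass interaction coefficients for {symbol} "
                     f"(Z={z}, A={a:.4f})\n")
            fh.write("# Generated by tools/make_coefficient_tables.py; "
                     "see that script for the physics sources.\n")
            fh.write("# columns: energy_keV photoelectric incoherent coherent "
                     "total energy_absorption   [cm^2/g]\n")
            for row in zip(e, pe, inc, coh, total, muen):
                fh.write(" ".join(f"{v:.6g}" for v in row) + "\n")
        print(f"{symbol}: {len(e)} rows")


if __name__ == "__main__":
    main()
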