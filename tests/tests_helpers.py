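"""Shared helpers for transport-level checks."""

import numpy as np

from mammodose.phantom import ADIPOSE, AIR, GLANDULAR, SKIN, PhantomSpec, \
    VoxelPhantom
from mammodose.spectrum import BeamConfig, EnergySpectrum
from mammodose.transport import TransportConfig, run_transport


def thin_slab_deposit_per_photon(registry, histories=200_000, seed=9):
    """Deposit per photon for a 20 keV broad beam on a 0.5 mm glandular
    slab (thin-slab collision-kerma geometry)."""
    spec = PhantomSpec(thickness_cm=0.05, glandular_fraction=0.5,
                       skin_mm=0.1, footprint_radius_cm=2.0, voxel_mm=0.5)
    h = 0.05
    shape = (int(round(4.0 / h)), int(round(2.0 / h)), 1)
    labels = np.full(shape, GLANDULAR, dtype=np.uint8)
    mats = {AIR: registry["air"], SKIN: registry["skin"],
            GLANDULAR: registry["glandular"], ADIPOSE: registry["adipose"]}
    ph = VoxelPhantom(spec, labels, 0.5, (-2.0, 0.0, 0.0), mats)
    beam = BeamConfig(paddle_mm=0.0, source_breast_cm=500.0)
    spect = EnergySpectrum(np.array([19.95]), np.array([1.0]))
    tal = run_transport(ph, spect, beam,
                        TransportConfig(histories=histories, batches=10,
                                        seed=seed, support_mm=0.0),
                        point_positions=[])
    return tal.batch_edep.sum() / tal.histories
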