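"""Calibration constants, pipeline defaults, and seed-stream derivation.

All physical constants used across the pipeline live here so that every
stage converts units the same way:

* ``SUBUNITS_PER_UM`` — an actin filament packs 370 subunits per micron
  of length; all subunit <-> micron conversions use exactly this value.
* ``FILAMENT_FOOTPRINT_UM2`` — the surface area swept by 1 micron of
  surface-adsorbed filament (0.006 um^2), used to convert a tether
  surface density (molecules/um^2) into tethers per micron of filament.
* ``KON0_BARBED`` / ``KOFF_BARBED`` — literature basal barbed-end
  association (11 subunits uM^-1 s^-1) and dissociation (2 s^-1) rates,
  the defaults of the Monte Carlo elongation model.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

SUBUNITS_PER_UM: float = 370.0
FILAMENT_FOOTPRINT_UM2: float = 0.006
KON0_BARBED: float = 11.0  # subunits uM^-1 s^-1
KOFF_BARBED: float = 2.0  # subunits s^-1
PAUSE_THRESHOLD: float = 1.5  # subunits/s; velocities above are "kinetically active"
SMOOTHING_WINDOW: int = 10  # samples in the running-mean velocity filter
LATTICE_SIZE: int = 100_000  # monomers in the Monte Carlo lattice

AVOGADRO: float = 6.02214076e23


def derive_seed(seed: int, label: str) -> int:
    """Derive a reproducible per-stage substream seed from a global seed.

    Hashing ``seed:label`` decorrelates substreams (e.g. tether placement
    for density index 3, replicate 7) while keeping every stream a pure
    function of the single global seed.  The result is < 2**31.
    """
    digest = hashlib.blake2b(f"{seed}:{label}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "little") % (2**31)


@dataclass
class PipelineConfig:
    """Defaults shared by the CLI and :func:`filakin.io.run_pipeline`."""

    pixel_size_um: float = 0.1
    frame_interval_s: float = 1.0
    subunits_per_um: float = SUBUNITS_PER_UM
    filament_footprint_um2: float = FILAMENT_FOOTPRINT_UM2
    pause_threshold: float = PAUSE_THRESHOLD
    smoothing_window: int = SMOOTHING_WINDOW
    kon0: float = KON0_BARBED
    koff: float = KOFF_BARBED
    lattice_size: int = LATTICE_SIZE
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in (
            "pixel_size_um",
            "frame_interval_s",
            "subunits_per_um",
            "filament_footprint_um2",
            "pause_threshold",
            "smoothing_window",
            "kon0",
            "koff",
            "lattice_size",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
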