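"""Named acquisition presets (geometry only, no data).

* ``sim-2.25MHz`` — the simulation geometry: 800 positions on a 41 mm circle,
  1500 samples per A-line at 25 MHz, 1500 m/s medium, 2.25 MHz / 70%
  bandwidth detector.
* ``phantom-nd:yag`` — the Nd:YAG phantom system shape after pair averaging:
  2400 positions, 1024 samples at 25 MHz.
* ``invivo-pld`` — the pulsed-laser-diode small-animal system shape:
  600 positions, 1024 samples at 25 MHz.
"""

from __future__ import annotations

from .core import ScanGeometry
from .forward import TransducerModel


def sim_geometry() -> ScanGeometry:
    return ScanGeometry(
        radius=41e-3,
        n_positions=800,
        angle_step=360.0 / 800,
        speed_of_sound=1500.0,
        sampling_frequency=25e6,
        n_samples=1500,
    )


def phantom_ndyag_geometry() -> ScanGeometry:
    return ScanGeometry(
        radius=41e-3,
        n_positions=2400,
        angle_step=360.0 / 2400,
        speed_of_sound=1500.0,
        sampling_frequency=25e6,
        n_samples=1024,
    )


def invivo_pld_geometry() -> ScanGeometry:
    return ScanGeometry(
        radius=41e-3,
        n_positions=600,
        angle_step=360.0 / 600,
        speed_of_sound=1500.0,
        sampling_frequency=25e6,
        n_samples=1024,
    )


def sim_transducer() -> TransducerModel:
    return TransducerModel(center_frequency=2.25e6, fractional_bandwidth=0.7)


PRESETS = {
    "sim-2.25MHz": sim_geometry,
    "phantom-nd:yag": phantom_ndyag_geometry,
    "invivo-pld": invivo_pld_geometry,
}
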