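#!/usr/bin/env python
"""Simulate the two reference scan conditions.

Produces a clean diagnostic-quality scan and a degraded CBCT-like scan of the
ACR head phantom and stores them under scratch/ (volumes are binary and
regenerable; every later stage can also re-simulate from the same seed).
"""

from pathlib import Path

from phantomqa import (
    clean_diagnostic_params,
    default_head_phantom,
    degraded_cbct_params,
    series_io,
    simulate_scan,
)

SEED = 1
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    SCRATCH.mkdir(exist_ok=True)
    spec = default_head_phantom()
    for name, params in (
        ("clean_head", clean_diagnostic_params(seed=SEED)),
        ("degraded_head", degraded_cbct_params(seed=SEED + 1)),
    ):
        vol = simulate_scan(spec, params)
        out = series_io.write_volume(vol, SCRATCH / name)
        print(
            f"{name}: {vol.shape[0]}x{vol.shape[1]}x{vol.shape[2]} voxels, "
            f"noise {params.noise_sd} HU, blur {params.blur_fwhm} mm, "
            f"cupping {params.cupping_amplitude} HU -> {out}"
        )


if __name__ == "__main__":
    main()
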