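"""Regenerate the shipped synthetic cone-fundamental fixture table.

Writes src/conegain/data/cone_fundamentals_synthetic.csv: Govardovskii A1
pigment templates behind a smooth lens/macular-like attenuation, with
pigment peaks solved so corneal peaks land at 559 (L), 530 (M), 426 (S) nm.
Deterministic; run from the repository root.
"""

from pathlib import Path

import numpy as np

from conegain.cones import corneal_sensitivity

OUT = Path(__file__).resolve().parents[1] / "src" / "conegain" / "data" \
    / "cone_fundamentals_synthetic.csv"


def main() -> None:
    wl = np.arange(380.0, 831.0, 1.0)
    cols = {peak: corneal_sensitivity(wl, peak) for peak in (559.0, 530.0, 426.0)}
    OUT.parent.mkdir(parents=True, exist_ok=True)
    with OUT.open("w") as f:
        f.write("wavelength_nm,L,M,S\n")
        for i, w in enumerate(wl):
            f.write(f"{w:.0f},{cols[559.0][i]:.6e},{cols[530.0][i]:.6e},"
                    f"{cols[426.0][i]:.6e}\n")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
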