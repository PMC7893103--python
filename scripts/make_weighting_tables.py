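"""Regenerate the bundled spectral weighting tables in src/circlight/data/.

Each table is written as two-column text (wavelength_nm, value) at 1-nm
resolution over 380-780 nm, with '#' provenance headers.

Sources:
* photopic_1924.tsv   — CIE 1924 2-deg photopic luminous efficiency V(lambda),
                        published 5-nm values, pchip-interpolated to 1 nm.
* scotopic_1951.tsv   — CIE 1951 scotopic V'(lambda), published 5-nm values
                        (plus the 507-nm unit maximum), pchip to 1 nm.
* scone_fundamental_synthetic.tsv — synthetic stand-in for a 2-deg corneal
                        S-cone fundamental (energy units, peak-normalized),
                        Stockman-Sharpe-like shape from 5-nm knots.
* macular_transmittance_synthetic.tsv — synthetic macular pigment
                        transmittance 10^(-OD), OD a two-Gaussian shape
                        peaking at 0.35 near 460 nm (2-deg field).
* lens_transmittance_synthetic.tsv — synthetic young-adult crystalline lens
                        transmittance from a two-component optical-density
                        tabulation (Pokorny-Smith-Lutze style, age ~32).

Run from the repository root:  python scripts/make_weighting_tables.py
"""

from pathlib import Path

import numpy as np
from scipy.interpolate import PchipInterpolator

OUT = Path(__file__).resolve().parents[1] / "src" / "circlight" / "data"
NM = np.arange(380.0, 781.0, 1.0)

# CIE 1924 photopic V(lambda), 5-nm published values
V_1924 = {
    380: 0.00004, 385: 0.00006, 390: 0.00012, 395: 0.00022, 400: 0.0004,
    405: 0.00064, 410: 0.00121, 415: 0.00218, 420: 0.0040, 425: 0.0073,
    430: 0.0116, 435: 0.01684, 440: 0.023, 445: 0.0298, 450: 0.038,
    455: 0.048, 460: 0.060, 465: 0.0739, 470: 0.09098, 475: 0.1126,
    480: 0.13902, 485: 0.1693, 490: 0.20802, 495: 0.2586, 500: 0.323,
    505: 0.4073, 510: 0.503, 515: 0.6082, 520: 0.710, 525: 0.7932,
    530: 0.862, 535: 0.91485, 540: 0.954, 545: 0.9803, 550: 0.99495,
    555: 1.0, 560: 0.995, 565: 0.9786, 570: 0.952, 575: 0.9154,
    580: 0.870, 585: 0.8163, 590: 0.757, 595: 0.6949, 600: 0.631,
    605: 0.5668, 610: 0.503, 615: 0.4412, 620: 0.381, 625: 0.321,
    630: 0.265, 635: 0.217, 640: 0.175, 645: 0.1382, 650: 0.107,
    655: 0.0816, 660: 0.061, 665: 0.04458, 670: 0.032, 675: 0.0232,
    680: 0.017, 685: 0.01192, 690: 0.00821, 695: 0.005723, 700: 0.004102,
    705: 0.002929, 710: 0.002091, 715: 0.001484, 720: 0.001047, 725: 0.00074,
    730: 0.00052, 735: 0.000361, 740: 0.000249, 745: 0.000172, 750: 0.00012,
    755: 0.000085, 760: 0.00006, 765: 0.00004, 770: 0.00003, 775: 0.00002,
    780: 0.000015,
}

# CIE 1951 scotopic V'(lambda), 5-nm published values + unit peak at 507 nm
VP_1951 = {
    380: 0.000589, 385: 0.001108, 390: 0.002209, 395: 0.00453, 400: 0.00929,
    405: 0.01852, 410: 0.03484, 415: 0.0604, 420: 0.0966, 425: 0.1436,
    430: 0.1998, 435: 0.2625, 440: 0.3281, 445: 0.3931, 450: 0.455,
    455: 0.513, 460: 0.567, 465: 0.620, 470: 0.676, 475: 0.734,
    480: 0.793, 485: 0.851, 490: 0.904, 495: 0.949, 500: 0.982,
    505: 0.998, 507: 1.0, 510: 0.997, 515: 0.975, 520: 0.935,
    525: 0.880, 530: 0.811, 535: 0.733, 540: 0.650, 545: 0.564,
    550: 0.481, 555: 0.402, 560: 0.3288, 565: 0.2639, 570: 0.2076,
    575: 0.1602, 580: 0.1212, 585: 0.0899, 590: 0.0655, 595: 0.0469,
    600: 0.03315, 605: 0.02312, 610: 0.01593, 615: 0.01088, 620: 0.00737,
    625: 0.00497, 630: 0.003335, 635: 0.002235, 640: 0.001497, 645: 0.001005,
    650: 0.000677, 655: 0.000459, 660: 0.0003129, 665: 0.0002146,
    670: 0.000148, 675: 0.0001026, 680: 0.0000715, 685: 0.0000501,
    690: 0.00003533, 695: 0.00002501, 700: 0.0000178, 705: 0.00001273,
    710: 0.00000914, 715: 0.0000066, 720: 0.00000478, 725: 0.000003482,
    730: 0.000002546, 735: 0.00000187, 740: 0.000001379, 745: 0.000001022,
    750: 0.00000076, 755: 0.000000567, 760: 0.000000425, 765: 0.00000032,
    770: 0.000000241, 775: 0.000000183, 780: 0.000000139,
}

# Synthetic 2-deg corneal S-cone fundamental knots (energy units, peak 1 at 440)
S_CONE = {
    380: 0.16, 385: 0.20, 390: 0.25, 395: 0.33, 400: 0.42, 405: 0.52,
    410: 0.62, 415: 0.72, 420: 0.81, 425: 0.88, 430: 0.94, 435: 0.98,
    440: 1.00, 445: 0.97, 450: 0.91, 455: 0.82, 460: 0.72, 465: 0.61,
    470: 0.50, 475: 0.40, 480: 0.31, 485: 0.23, 490: 0.165, 495: 0.115,
    500: 0.078, 505: 0.052, 510: 0.034, 515: 0.022, 520: 0.014, 525: 0.0085,
    530: 0.0052, 535: 0.0032, 540: 0.0019, 545: 0.0012, 550: 0.0007,
    555: 0.00042, 560: 0.00025, 565: 0.00016, 570: 0.0001, 575: 0.00006,
    580: 0.00004, 590: 0.000015, 600: 0.000006, 620: 0.0000009, 650: 0.0,
    780: 0.0,
}

# Synthetic young-adult lens optical density knots: two components
# (Pokorny-Smith-Lutze style; density = TL1 + TL2 at age ~32)
LENS_WL = [380, 390, 400, 410, 420, 430, 440, 450, 460, 470, 480, 490, 500,
           510, 520, 530, 540, 550, 560, 570, 580, 590, 600, 610, 620, 650, 780]
LENS_TL1 = [0.744, 0.668, 0.600, 0.510, 0.433, 0.377, 0.327, 0.295, 0.267,
            0.233, 0.207, 0.187, 0.167, 0.147, 0.133, 0.120, 0.107, 0.093,
            0.080, 0.067, 0.053, 0.040, 0.027, 0.013, 0.0, 0.0, 0.0]
LENS_TL2 = [2.493, 1.735, 1.000, 0.583, 0.300, 0.116, 0.033, 0.005, 0, 0, 0,
            0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]


def _pchip(tab: dict[int | float, float]) -> np.ndarray:
    wl = np.array(sorted(tab), dtype=float)
    v = np.array([tab[k] for k in sorted(tab)], dtype=float)
    return np.clip(PchipInterpolator(wl, v)(NM), 0.0, None)


def _write(fname: str, values: np.ndarray, header: str) -> None:
    lines = [f"# {line}" for line in header.strip().splitlines()]
    lines.append("# wavelength_nm\tvalue")
    for wl, v in zip(NM, values):
        lines.append(f"{wl:.0f}\t{v:.6g}")
    (OUT / fname).write_text("\n".join(lines) + "\n")
    print(f"wrote {fname} ({len(values)} rows)")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    _write(
        "photopic_1924.tsv",
        _pchip(V_1924),
        "CIE 1924 2-deg photopic luminous efficiency V(lambda).\n"
        "Published 5-nm values, monotone-cubic (pchip) interpolated to 1 nm.",
    )
    _write(
        "scotopic_1951.tsv",
        _pchip(VP_1951),
        "CIE 1951 scotopic luminous efficiency V'(lambda).\n"
        "Published 5-nm values plus the 507-nm unit maximum, pchip to 1 nm.",
    )
    _write(
        "scone_fundamental_synthetic.tsv",
        _pchip(S_CONE),
        "Synthetic stand-in for a 2-deg corneal S-cone fundamental\n"
        "(energy units, peak-normalized; Stockman-Sharpe-like shape).\n"
        "Includes lens and macular screening, i.e. as measured at the cornea.",
    )
    mp_od = np.exp(-((NM - 458.0) ** 2) / (2 * 22.0**2)) + 0.3 * np.exp(
        -((NM - 485.0) ** 2) / (2 * 15.0**2)
    )
    mp_od = 0.35 * mp_od / mp_od.max()
    _write(
        "macular_transmittance_synthetic.tsv",
        10.0 ** (-mp_od),
        "Synthetic macular pigment transmittance 10^(-OD), 2-deg field.\n"
        "OD: two-Gaussian shape (main lobe 458 nm, shoulder 485 nm), peak 0.35.",
    )
    lens_od = PchipInterpolator(
        np.array(LENS_WL, dtype=float),
        np.array(LENS_TL1) + np.array(LENS_TL2),
    )(NM)
    _write(
        "lens_transmittance_synthetic.tsv",
        10.0 ** (-np.clip(lens_od, 0.0, None)),
        "Synthetic young-adult crystalline lens transmittance 10^(-OD).\n"
        "OD from a two-component tabulation (Pokorny-Smith-Lutze style, age ~32),\n"
        "pchip-interpolated knots; short-wavelength end extrapolated smoothly.",
    )


if __name__ == "__main__":
    main()
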