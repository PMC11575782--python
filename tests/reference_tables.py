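"""Published derived-constant tables frozen as test expectations.

``RD_PRINTED`` and ``SUBSTRATE_PRINTED`` hold the printed derived values the
rate pipeline must reproduce from the measured inputs, as strings so each
cell knows its own printed precision. Two print errata are corrected here
(and only here — the pipeline never reads these tables):

- the E255K/imatinib dissociation constant was printed as 12021 nM, a
  decimal shift of the formula value 3174/2.641 = 1202 nM;
- the imatinib and ponatinib on-rate (konR) columns were swapped in print;
  ``KONR_PRINTED``/``KOFFR_PRINTED`` list them under the correct drug.

konR/koffR cells were printed after intermediate rounding, so they carry a
looser relative tolerance than the last-digit rule used for RD.
"""

from __future__ import annotations

# R_D in nM, printed precision implied by the string.
RD_PRINTED: dict[tuple[str, str], str] = {
    ("Wild-type", "imatinib"): "203.6",
    ("Wild-type", "ponatinib"): "0.811",
    ("Wild-type", "dasatinib"): "0.695",
    ("G250E", "imatinib"): "1338",
    ("G250E", "ponatinib"): "4.63",
    ("G250E", "dasatinib"): "3.00",
    ("E255K", "imatinib"): "1202",  # decimal-shift erratum; printed 12021
    ("E255K", "ponatinib"): "6.66",
    ("E255K", "dasatinib"): "3.90",
    ("E255V", "imatinib"): "3651",
    ("E255V", "ponatinib"): "11.1",
    ("E255V", "dasatinib"): "2.57",
    ("T315I", "imatinib"): "2721",
    ("T315I", "ponatinib"): "1.86",
    ("T315I", "dasatinib"): "40.5",
    ("T315M", "imatinib"): "1410",
    ("T315M", "ponatinib"): "79.5",
    ("T315M", "dasatinib"): "106",
    ("Y253H-E255V", "imatinib"): "628.8",
    ("Y253H-E255V", "ponatinib"): "12.5",
    ("Y253H-E255V", "dasatinib"): "1.11",
}

# (koffS min^-1, konS uM^-1 min^-1) per variant.
SUBSTRATE_PRINTED: dict[str, tuple[str, str]] = {
    "Wild-type": ("33.0", "5.82"),
    "G250E": ("350", "36.8"),
    "E255K": ("127", "12.2"),
    "E255V": ("122", "5.82"),
    "T315I": ("29.7", "5.82"),
    "T315M": ("16.2", "12.8"),
    "Y253H-E255V": ("26.4", "56.6"),
}

# konR in 1e-3 nM^-1 min^-1, column transposition corrected.
KONR_PRINTED: dict[tuple[str, str], float] = {
    ("Wild-type", "imatinib"): 0.290,
    ("Wild-type", "ponatinib"): 6.01,
    ("Wild-type", "dasatinib"): 3.35,
    ("G250E", "imatinib"): 0.0441,
    ("G250E", "ponatinib"): 1.05,
    ("G250E", "dasatinib"): 3.35,
    ("E255K", "imatinib"): 0.0491,
    ("E255K", "ponatinib"): 0.732,
    ("E255K", "dasatinib"): 3.35,
    ("E255V", "imatinib"): 0.0162,
    ("E255V", "ponatinib"): 0.440,
    ("E255V", "dasatinib"): 3.35,
    ("T315I", "imatinib"): 0.0217,
    ("T315I", "ponatinib"): 2.63,
    ("T315I", "dasatinib"): 3.35,
    ("T315M", "imatinib"): 0.0419,
    ("T315M", "ponatinib"): 0.0614,
    ("T315M", "dasatinib"): 7.37,
    ("Y253H-E255V", "imatinib"): 0.0938,
    ("Y253H-E255V", "ponatinib"): 0.391,
    ("Y253H-E255V", "dasatinib"): 3.35,
}

# koffR in 1e-3 min^-1 (constant per drug for the inactive binders).
KOFFR_PRINTED: dict[tuple[str, str], float] = {
    ("Wild-type", "dasatinib"): 2.33,
    ("G250E", "dasatinib"): 10.1,
    ("E255K", "dasatinib"): 13.1,
    ("E255V", "dasatinib"): 8.61,
    ("T315I", "dasatinib"): 136.0,
    ("T315M", "dasatinib"): 779.0,
    ("Y253H-E255V", "dasatinib"): 3.72,
    **{(v, d): {"imatinib": 59.0, "ponatinib": 4.88}[d]
       for v in SUBSTRATE_PRINTED
       for d in ("imatinib", "ponatinib")},
}

# Printed dosing constants per drug: (Gamma nM, alpha, epsilon).
PK_PRINTED: dict[str, tuple[str, str, str]] = {
    "imatinib": ("2112.46", "6.28e9", "2.52"),
    "ponatinib": ("70.65", "3.72e13", "2"),
    "dasatinib": ("163.73", "1.37e18", "64"),
}


def ulp(printed: str) -> float:
    """One unit in the last printed digit of a decimal string."""
    s = printed.lower()
    mant, exp = (s.split("e") + ["0"])[:2]
    decimals = len(mant.split(".")[1]) if "." in mant else 0
    return 10.0 ** (int(exp) - decimals)


def assert_printed(computed: float, printed: str, n_ulp: float = 1.0) -> None:
    target = float(printed)
    tol = n_ulp * ulp(printed)
    assert abs(computed - target) <= tol, (
        f"computed {computed!r} differs from printed {printed} "
        f"by more than {n_ulp} ulp ({tol})"
    )
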