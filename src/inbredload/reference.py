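"""Published summary statistics for the Rubia Gallega beef cattle population.

These printed values (trait means/SDs and posterior estimates of the
depression regression and variance components) are inputs to the derived
arithmetic — depression percentages, heritabilities and the load-variance
ratio at a reference inbreeding level — not quantities this package estimates.
Units: kg for BW/WW/CCW, score units for CONF/FAT, days for CI/AFP.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class TraitSummary:
    trait: str
    n_records: int
    mean: float
    sd: float
    d: float  # posterior mean of the depression regression (at F = 1)
    d_psd: float
    sigma_u2: float
    sigma_i2: float
    sigma_ui: float
    sigma_h2: float
    sigma_e2: float
    sigma_p2: float = 0.0


PUBLISHED = {
    "BW": TraitSummary("BW", 369_226, 42.65, 7.02, -1.20, 0.33, 9.27, 57.97, -11.03, 7.89, 29.49),
    "WW": TraitSummary(
        "WW", 113_869, 287.87, 47.71, -33.14, 4.97, 450.64, 1907.93, -547.68, 251.86, 980.22
    ),
    "CCW": TraitSummary(
        "CCW", 107_110, 224.58, 41.23, -59.29, 3.91, 476.50, 7965.10, -847.18, 302.00, 456.65
    ),
    "CONF": TraitSummary(
        "CONF", 107_046, 10.95, 1.99, -0.88, 0.22, 1.43, 25.61, -3.26, 0.27, 1.59
    ),
    "FAT": TraitSummary(
        "FAT", 106_962, 5.76, 1.33, -0.86, 0.14, 0.58, 10.78, -1.85, 0.10, 1.01
    ),
    "CI": TraitSummary(
        "CI", 278_330, 401.42, 61.74, 30.24, 6.38, 199.36, 7356.46, -460.15, 264.29, 3080.66,
        sigma_p2=208.33,
    ),
    "AFP": TraitSummary(
        "AFP", 51_229, 865.85, 136.38, 74.27, 34.11, 4298.96, 194_546.51, -12_964.96, 2414.99,
        11_985.86,
    ),
}

#: published depression percentages (of the mean / of the SD) for cross-checks
PUBLISHED_DPM = {
    "BW": 2.81, "WW": 11.51, "CCW": 26.40, "CONF": 8.01, "FAT": 14.93, "CI": 7.53, "AFP": 8.58,
}
PUBLISHED_DPSD = {
    "BW": 17.09, "WW": 69.46, "CCW": 143.80, "CONF": 44.22, "FAT": 64.66, "CI": 48.98,
    "AFP": 54.45,
}
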