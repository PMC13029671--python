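"""Published study-level summary tables used as inputs.

``SOIL_SUMMARY`` holds the reported rhizosphere soil physicochemical
means +/- standard errors (n = 6 composite samples) for the three
halophytes: KC (*Kalidium cuspidatum*), NT (*Nitraria tangutorum*) and
RS (*Reaumuria soongarica*).  These are the default generative
parameters of the soil simulator.

``NETWORK_SUMMARY`` holds the reported whole-network parameters of the
three bacterial-fungal co-occurrence networks (one per plant group, built
at |rho| > 0.9, p < 0.01).
"""

from __future__ import annotations

import pandas as pd

#: variable -> group -> (mean, SE); units: pH unitless, SWC %, Na/K/AN/OP
#: and the microbial biomass pools mg/kg, TC/TOC/TN/TP g/kg
SOIL_SUMMARY: dict[str, dict[str, tuple[float, float]]] = {
    "pH":  {"KC": (8.81, 0.04),   "NT": (8.47, 0.05),    "RS": (8.29, 0.06)},
    "SWC": {"KC": (27.76, 1.08),  "NT": (21.92, 0.86),   "RS": (19.76, 0.20)},
    "Na":  {"KC": (5728.9, 451.97), "NT": (1384.43, 122.46), "RS": (580.15, 35.26)},
    "K":   {"KC": (58.16, 4.47),  "NT": (34.49, 1.85),   "RS": (28.28, 1.90)},
    "TC":  {"KC": (6.91, 0.60),   "NT": (10.77, 0.77),   "RS": (13.34, 0.27)},
    "TOC": {"KC": (2.93, 0.21),   "NT": (5.49, 0.44),    "RS": (6.37, 0.62)},
    "TN":  {"KC": (0.25, 0.01),   "NT": (0.49, 0.10),    "RS": (0.35, 0.03)},
    "TP":  {"KC": (0.34, 0.02),   "NT": (0.37, 0.03),    "RS": (0.29, 0.02)},
    "AN":  {"KC": (6.10, 0.30),   "NT": (9.26, 0.42),    "RS": (11.52, 0.58)},
    "OP":  {"KC": (0.91, 0.03),   "NT": (0.60, 0.05),    "RS": (0.54, 0.03)},
    "MBC": {"KC": (38.92, 1.69),  "NT": (45.72, 0.76),   "RS": (51.16, 2.23)},
    "MBN": {"KC": (2.56, 0.08),   "NT": (2.74, 0.06),    "RS": (3.22, 0.24)},
    "MBP": {"KC": (0.72, 0.02),   "NT": (0.87, 0.02),    "RS": (0.91, 0.03)},
}

#: reported sample size behind each group mean
SOIL_SUMMARY_N = 6


def soil_summary_frames() -> tuple[pd.DataFrame, pd.DataFrame]:
    """(means, SEs) DataFrames, variables x groups."""
    means = pd.DataFrame({g: {v: SOIL_SUMMARY[v][g][0] for v in SOIL_SUMMARY}
                          for g in ("KC", "NT", "RS")})
    ses = pd.DataFrame({g: {v: SOIL_SUMMARY[v][g][1] for v in SOIL_SUMMARY}
                        for g in ("KC", "NT", "RS")})
    return means.loc[list(SOIL_SUMMARY)], ses.loc[list(SOIL_SUMMARY)]


NETWORK_SUMMARY = pd.DataFrame(
    {
        "KC": [424, 6, 2392, 2330, 62, 0.69, 21, 6.57, 16.82, 0.02, 0.56, 0.15],
        "NT": [273, 95, 2996, 2934, 62, 0.40, 28, 4.72, 16.01, 0.04, 0.59, 0.05],
        "RS": [574, 59, 3300, 3154, 146, 0.64, 18, 5.84, 15.93, 0.02, 0.51, 0.04],
    },
    index=[
        "bacterial_nodes", "fungal_nodes", "edges", "positive_edges",
        "negative_edges", "modularity", "n_modules", "avg_path_length",
        "diameter", "density", "clustering_coefficient",
        "betweenness_centralization",
    ],
)
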