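"""Published summary tables from a four-season maize FAW screening trial.

A multi-season screen-house evaluation of 192 maize hybrids (with commercial
checks WH401 and WH505) under artificial fall-armyworm infestation published
per-trait variance components and the top-15 / bottom-5 hybrid rankings
under three selection schemes (PC1-based index, PC2-based index, and direct
selection on mean leaf damage).  Those printed summaries are embedded here
as reference inputs for replication-style analyses: set arithmetic over the
published selections, closed-form heritability checks, and fixed-weight
index construction.

Values are transcribed as printed (2 decimal places); nothing here is
computed by this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "VARIANCE_COMPONENTS",
    "TOP15",
    "BOTTOM5",
    "FIXED_INDEX_WEIGHTS",
    "PUBLISHED_LOADINGS",
    "top15_frame",
]

#: per trait: (grand mean, sigmaG2, sigmaGE2, sigmae2, published H2, CV%)
VARIANCE_COMPONENTS: dict[str, tuple[float, float, float, float, float, float]] = {
    "LD1": (3.52, 0.03, 0.02, 0.12, 0.62, 9.71),
    "LD2": (6.04, 0.04, 0.01, 0.11, 0.73, 5.53),
    "LD3": (5.72, 0.05, 0.00, 0.27, 0.59, 9.12),
    "LD_AV": (5.09, 0.04, 0.00, 0.07, 0.79, 5.28),
    "ED": (1.98, 0.04, 0.02, 0.18, 0.59, 21.27),
    "ER": (8.14, 11.03, 3.33, 28.80, 0.65, 65.91),
    "GY": (5.11, 0.88, 0.72, 1.70, 0.69, 25.55),
}

#: published coefficient vectors of the two PC-based indices (trait order
#: LD1, LD2, LD3, ED, ER, GY), already on the max-|weight| = 1 convention.
FIXED_INDEX_WEIGHTS: dict[str, dict[str, float]] = {
    "PC1BI": {"LD1": -0.95, "LD2": -0.93, "LD3": -0.91, "ED": -0.50, "ER": -0.70, "GY": 1.00},
    "PC2BI": {"LD1": -0.36, "LD2": -0.44, "LD3": -0.45, "ED": 1.00, "ER": 0.83, "GY": -0.08},
}

#: published rescaled loadings of the first two components (correlation-matrix
#: PCA; PC1 explains 64.2 % of the variance, PC2 32.9 %).
PUBLISHED_LOADINGS: dict[str, dict[str, float]] = {
    "PC1": {"LD1": -0.97, "LD2": -0.98, "LD3": -0.93, "ED": -0.19, "ER": -0.39, "GY": 1.00},
    "PC2": {"LD1": 0.10, "LD2": 0.25, "LD3": 0.30, "ED": -1.00, "ER": -0.94, "GY": 0.05},
}

# Published top-15 panels: per scheme, rank-ordered rows
# (hybrid, LD_AV, ED, ER, GY, index value or None for direct selection).
TOP15: dict[str, list[tuple[str, float, float, float, float, float | None]]] = {
    "PC1BI": [
        ("E154", 4.8, 1.7, 2.5, 6.5, -8.7),
        ("E163", 4.6, 1.7, 2.5, 5.1, -9.3),
        ("E133", 4.9, 2.1, 7.2, 7.8, -9.4),
        ("E116", 4.9, 1.7, 2.9, 6.1, -9.5),
        ("E141", 4.7, 2.2, 7.9, 7.6, -9.5),
        ("E78", 4.9, 1.9, 5.6, 7.0, -9.6),
        ("E159", 5.0, 1.9, 7.0, 7.7, -9.7),
        ("E34", 4.9, 1.5, 4.1, 6.2, -9.8),
        ("E148", 4.8, 1.8, 4.1, 5.8, -9.8),
        ("E74", 5.2, 1.6, 3.8, 6.8, -9.8),
        ("E161", 4.9, 1.7, 2.9, 5.7, -9.9),
        ("E115", 5.0, 1.8, 7.0, 7.4, -10.0),
        ("E181", 4.8, 2.1, 7.5, 7.0, -10.2),
        ("E111", 5.1, 1.7, 5.3, 6.6, -10.3),
        ("E183", 4.7, 1.8, 5.2, 5.7, -10.3),
    ],
    "PC2BI": [
        ("E28", 5.1, 1.4, 1.1, 5.0, 1.4),
        ("E155", 4.8, 1.6, 1.7, 4.1, 0.3),
        ("E156", 4.9, 1.7, 2.4, 4.5, -0.3),
        ("E154", 4.8, 1.7, 2.5, 6.5, -0.3),
        ("E163", 4.6, 1.7, 2.5, 5.1, -0.5),
        ("E12", 5.3, 1.6, 3.2, 5.3, -0.7),
        ("E161", 4.9, 1.7, 2.9, 5.7, -0.7),
        ("E116", 4.9, 1.7, 2.9, 6.1, -0.8),
        ("E1", 5.2, 1.7, 3.3, 4.7, -1.0),
        ("E172", 5.3, 1.6, 3.5, 4.1, -1.0),
        ("E74", 5.2, 1.6, 3.8, 6.8, -1.2),
        ("E126", 5.1, 1.8, 3.4, 4.0, -1.2),
        ("E18", 4.9, 1.7, 3.5, 5.0, -1.3),
        ("E38", 5.3, 1.7, 3.7, 3.0, -1.4),
        ("E130", 5.2, 1.7, 3.8, 5.9, -1.5),
    ],
    "LD_AV": [
        ("E163", 4.6, 1.7, 2.5, 5.1, None),
        ("E152", 4.7, 1.6, 3.8, 4.4, None),
        ("E146", 4.7, 1.6, 6.1, 4.1, None),
        ("E164", 4.7, 1.7, 3.7, 4.3, None),
        ("E165", 4.7, 1.9, 9.2, 4.7, None),
        ("E141", 4.7, 2.2, 7.9, 7.6, None),
        ("E183", 4.7, 1.8, 5.2, 5.7, None),
        ("E169", 4.7, 2.1, 6.6, 5.2, None),
        ("E148", 4.8, 1.8, 4.1, 5.8, None),
        ("E139", 4.8, 2.0, 7.8, 4.7, None),
        ("E185", 4.8, 1.9, 7.3, 5.7, None),
        ("E89", 4.8, 2.2, 11.4, 4.2, None),
        ("E117", 4.8, 2.3, 12.8, 5.7, None),
        ("E170", 4.8, 2.0, 4.6, 4.9, None),
        ("E155", 4.8, 1.6, 1.7, 4.1, None),
    ],
}

#: published bottom-5 panels per scheme (hybrid, LD_AV, ED, ER, GY).
BOTTOM5: dict[str, list[tuple[str, float, float, float, float]]] = {
    "PC1BI": [
        ("E189", 5.6, 2.6, 20.0, 5.1),
        ("E188", 5.0, 2.5, 20.5, 3.5),
        ("E127", 5.0, 2.9, 23.9, 2.8),
        ("E192", 6.1, 2.3, 17.4, 3.1),
        ("E191", 6.2, 2.7, 31.3, 4.4),
    ],
    "PC2BI": [
        ("E140", 5.1, 2.5, 19.2, 5.7),
        ("E189", 5.6, 2.6, 20.0, 5.1),
        ("E188", 5.0, 2.5, 20.5, 3.5),
        ("E127", 5.0, 2.9, 23.9, 2.8),
        ("E191", 6.2, 2.7, 31.3, 4.4),
    ],
    "LD_AV": [
        ("E41", 5.6, 2.0, 3.9, 3.4),
        ("E189", 5.6, 2.6, 20.0, 5.1),
        ("E2", 5.6, 1.8, 5.9, 2.7),
        ("E192", 6.1, 2.3, 17.4, 3.1),
        ("E191", 6.2, 2.7, 31.3, 4.4),
    ],
}


def top15_frame(scheme: str) -> pd.DataFrame:
    """Published top-15 panel for a scheme as a rank-indexed DataFrame."""
    rows = TOP15[scheme]
    frame = pd.DataFrame(
        rows, columns=["genotype", "LD_AV", "ED", "ER", "GY", "value"]
    )
    frame.index = pd.RangeIndex(1, len(rows) + 1, name="rank")
    return frame
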