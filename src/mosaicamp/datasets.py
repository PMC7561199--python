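"""Bundled reference dataset: per-embryo measurements from an Fgf10-CRISPR
founder (F0) mouse study.

Embryos are classified by limb phenotype — type I (no limbs), type II (limb
defects), type III (normal limbs) — and genotyped by amplicon deep sequencing
of neck-skin, lung and/or limb-dermis DNA.  The tables bundle, per embryo:

* the functional-genotype percentage per sequenced tissue (reads that are wild
  type or in-frame with the Lys196/His201 codons retained);
* terminal-tubule density (count per mm^2 of lung section, E16.5);
* SPC-positive cell percentage (alveolar type 2 cells over total counted
  cells, mean +/- SEM over eight fields, E18.5);
* embryo weight in grams (E18.5);
* cross-tissue read-count contingency tables for the concordance test.

These are measured values from a published study design, embedded so the
statistical layer can be exercised and validated offline; missing entries are
NaN/None.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .concordance import ContingencyTable


def e165_embryos() -> pd.DataFrame:
    """E16.5 embryos: limb type, terminal-tubule density (per mm^2) and
    functional-genotype percentage in neck DNA."""
    rows = [
        ("I", "#9", 0.0, 0.00),
        ("I", "#5", 0.0, 4.63),
        ("I", "#7", 18.7, 20.35),
        ("II", "#11", 87.4, 20.60),
        ("II", "#3", 59.0, 25.39),
        ("II", "#4", 106.8, 29.96),
        ("III", "#1", 113.4, 42.83),
        ("III", "#2", 127.1, 46.97),
        ("III", "#8", 122.2, 73.06),
        ("WT", "#1", 131.2, np.nan),
        ("WT", "#2", 117.9, np.nan),
        ("WT", "#3", 157.6, np.nan),
    ]
    return pd.DataFrame(
        rows,
        columns=["type", "embryo_id", "tubule_density", "functional_percent_neck"],
    )


def e185_embryos() -> pd.DataFrame:
    """E18.5 embryos: limb type, weight (g), SPC-positive percentage (mean and
    SEM over fields, where immunostained) and functional-genotype percentage
    per sequenced tissue."""
    rows = [
        # type, id, weight, spc_mean, spc_sem, neck, lung, limb
        ("I", "#18", 0.6303, np.nan, np.nan, 9.27, np.nan, np.nan),
        ("I", "#19", 0.6899, np.nan, np.nan, 0.50, np.nan, np.nan),
        ("I", "#26", 0.4682, np.nan, np.nan, 0.45, np.nan, np.nan),
        ("II", "#14", 0.5784, np.nan, np.nan, 32.96, np.nan, np.nan),
        ("III", "#11", 0.7799, np.nan, np.nan, 67.75, 61.19, 64.23),
        ("III", "#12", 0.9111, np.nan, np.nan, np.nan, 65.98, 66.45),
        ("III", "#13", 0.9699, np.nan, np.nan, np.nan, 82.59, 84.77),
        ("III", "#15", 0.9572, np.nan, np.nan, 59.78, 56.84, 56.22),
        ("III", "#16", 0.9254, np.nan, np.nan, np.nan, 100.00, 100.00),
        ("III", "#17", 0.7524, np.nan, np.nan, np.nan, 70.11, 64.00),
        ("III", "#20", 1.0555, 19.9, 0.7, 100.00, np.nan, 100.00),
        ("III", "#21", 0.7742, 16.9, 0.8, 56.92, np.nan, 57.52),
        ("III", "#22", 0.8757, 9.8, 0.5, 28.92, np.nan, 29.94),
        ("III", "#23", 0.9232, 24.2, 0.8, 100.00, np.nan, 97.20),
        ("III", "#24", 0.9976, 18.8, 0.7, 73.06, np.nan, 82.26),
        ("III", "#25", 0.9832, 15.2, 1.4, 40.75, np.nan, 40.16),
        ("WT", "#2", 0.7472, np.nan, np.nan, 99.63, 100.00, 100.00),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "type",
            "embryo_id",
            "weight_g",
            "spc_positive_percent",
            "spc_positive_sem",
            "functional_percent_neck",
            "functional_percent_lung",
            "functional_percent_limb",
        ],
    )


def tissue_read_counts() -> dict[str, ContingencyTable]:
    """Cross-tissue genotype read-count contingency tables (E18.5 deep
    sequencing), keyed by embryo id.  Row labels follow the category pooling
    used per embryo: Wt (wild type), In (w) (in-frame, critical codons
    retained), Out (frameshift), W/o & Out (non-functional in-frame plus
    frameshift)."""
    spec: dict[str, tuple[tuple[str, ...], tuple[str, ...], list[list[int]]]] = {
        "#2": (("Wt", "Out"), ("neck", "lung", "limb"),
               [[4877, 8760, 58889], [18, 0, 0]]),
        "#11": (("Wt", "Out"), ("neck", "lung", "limb"),
                [[6686, 12893, 18549], [3182, 8178, 10331]]),
        "#12": (("Wt", "Out"), ("lung", "limb"),
                [[706, 19627], [364, 9911]]),
        "#13": (("Wt", "Out"), ("lung", "limb"),
                [[4203, 45331], [886, 8147]]),
        "#15": (("Wt", "W/o & Out"), ("neck", "lung", "limb"),
                [[7295, 20266, 22243], [4908, 15388, 17318]]),
        "#16": (("Wt", "Out"), ("lung", "limb"),
                [[15698, 38223], [0, 0]]),
        "#17": (("Wt", "In (w)", "Out"), ("lung", "limb"),
                [[3441, 21706], [2869, 13857], [2690, 20007]]),
        "#20": (("Wt", "In (w)"), ("neck", "limb"),
                [[29282, 5549], [11875, 2653]]),
        "#21": (("Wt", "Out"), ("neck", "limb"),
                [[23077, 10726], [17464, 7923]]),
        "#22": (("Wt", "Out"), ("neck", "limb"),
                [[2653, 963], [6521, 2253]]),
        "#23": (("Wt", "Out"), ("neck", "limb"),
                [[82324, 1146], [0, 33]]),
        "#24": (("Wt", "Out"), ("neck", "limb"),
                [[8862, 2633], [3268, 568]]),
        "#25": (("In (w)", "Out"), ("neck", "limb"),
                [[12665, 10417], [18415, 15520]]),
    }
    out: dict[str, ContingencyTable] = {}
    for embryo_id, (row_labels, col_labels, counts) in spec.items():
        out[embryo_id] = ContingencyTable(
            embryo_id=embryo_id,
            row_labels=row_labels,
            col_labels=col_labels,
            counts=np.asarray(counts, dtype=np.int64),
        )
    return out
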