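"""Cross-tissue concordance of genotype composition.

For one embryo, read counts per genotype category form a categories x tissues
contingency table; a Pearson chi-square test (no continuity correction) asks
whether the mutation composition differs between tissues.  Following standard
practice, the test is flagged not-applicable (reported "N.A.") whenever any
expected frequency falls below 5 — the statistic is still returned.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classification import AlleleCategory, GenotypeComposition

#: default pooling: wild type, functional in-frame, and everything else pooled
DEFAULT_SCHEME = {
    "Wt": (AlleleCategory.WILD_TYPE,),
    "In (w)": (AlleleCategory.INFRAME_FUNCTIONAL,),
    "W/o & Out": (
        AlleleCategory.INFRAME_NONFUNCTIONAL,
        AlleleCategory.FRAMESHIFT,
        AlleleCategory.LARGE_INSERTION,
    ),
}


@dataclass(frozen=True)
class ContingencyTable:
    embryo_id: str
    row_labels: tuple[str, ...]
    col_labels: tuple[str, ...]
    counts: np.ndarray  # rows x cols, non-negative ints

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match labels")
        if (c < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.row_labels) < 2 or len(self.col_labels) < 2:
            raise ValueError("contingency table needs >= 2 rows and >= 2 columns")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=list(self.row_labels), columns=list(self.col_labels)
        )


@dataclass(frozen=True)
class ChiSquareResult:
    statistic: float
    df: int
    p_value: float
    expected: np.ndarray
    min_expected: float
    applicable: bool

    def format_p(self) -> str:
        """p-value formatting: scientific notation below 1e-4, N.A. when the
        expected-frequency rule fires."""
        if not self.applicable:
            return "N.A."
        if self.p_value < 1e-4:
            return f"{self.p_value:.0E}"
        return f"{self.p_value:.4g}"


def pool_categories(
    compositions: dict[str, GenotypeComposition],
    embryo_id: str = "",
    scheme: dict[str, tuple[AlleleCategory, ...]] | None = None,
) -> ContingencyTable:
    """Build a categories x tissues read-count table from per-tissue
    compositions, pooling categories per ``scheme`` (default keeps wild type
    and functional in-frame separate and pools the rest), then dropping
    all-zero rows."""
    if len(compositions) < 2:
        raise ValueError("need compositions from >= 2 tissues")
    if scheme is None:
        scheme = DEFAULT_SCHEME
    tissues = list(compositions)
    rows = []
    labels = []
    for label, cats in scheme.items():
        row = []
        for t in tissues:
            comp = compositions[t]
            if comp.counts is None:
                raise ValueError(
                    f"composition for tissue {t!r} lacks raw read counts"
                )
            row.append(sum(comp.counts.get(c, 0) for c in cats))
        rows.append(row)
        labels.append(label)
    counts = np.asarray(rows, dtype=np.int64)
    nonzero = counts.sum(axis=1) > 0
    counts = counts[nonzero]
    labels = [l for l, keep in zip(labels, nonzero) if keep]
    if counts.shape[0] < 2:
        raise ValueError(
            f"embryo {embryo_id or '?'}: fewer than 2 genotype categories observed"
        )
    return ContingencyTable(
        embryo_id=embryo_id,
        row_labels=tuple(labels),
        col_labels=tuple(tissues),
        counts=counts,
    )


def expected_frequencies(table: ContingencyTable) -> np.ndarray:
    """Expected cell counts under independence: row total x column total / N.
    Margins of the expected matrix equal the observed margins exactly."""
    counts = np.asarray(table.counts, dtype=float)
    grand = counts.sum()
    if grand <= 0:
        raise ValueError("zero grand total")
    return np.outer(counts.sum(axis=1), counts.sum(axis=0)) / grand


def chi_square(table: ContingencyTable) -> ChiSquareResult:
    """Pearson chi-square test of homogeneity across tissues, without
    continuity correction.  ``applicable`` is False when any expected
    frequency is below 5 (reported as N.A.); the statistic is still
    computed."""
    counts = np.asarray(table.counts, dtype=float)
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("degenerate table: zero row or column margin")
    statistic, p_value, df, expected = stats.chi2_contingency(
        counts, correction=False
    )
    min_expected = float(expected.min())
    return ChiSquareResult(
        statistic=float(statistic),
        df=int(df),
        p_value=float(p_value),
        expected=expected,
        min_expected=min_expected,
        applicable=min_expected >= 5.0,
    )


def concordance_report(
    tables: list[ContingencyTable],
) -> pd.DataFrame:
    """Per-embryo concordance summary: statistic, df, p (or N.A.), minimum
    expected frequency."""
    rows = []
    for t in tables:
        res = chi_square(t)
        rows.append(
            {
                "embryo_id": t.embryo_id,
                "tissues": ",".join(t.col_labels),
                "categories": ",".join(t.row_labels),
                "statistic": res.statistic,
                "df": res.df,
                "p_value": res.p_value,
                "p_reported": res.format_p(),
                "min_expected": res.min_expected,
                "applicable": res.applicable,
            }
        )
    return pd.DataFrame(rows)
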