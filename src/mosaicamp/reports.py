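"""Headline analyses of the bundled founder-embryo dataset.

Recomputes, from the per-embryo tables in :mod:`mosaicamp.datasets`, the
study-level statistics: functional-genotype group summaries, terminal-tubule
density summaries, dose-phenotype Pearson correlations, the omnibus ANOVA on
the E16.5 functional-percentage groups, Dunnett's test of tubule density
against wild type, and the cross-tissue chi-square concordance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import datasets
from .concordance import chi_square
from .phenotype_stats import (
    dunnett_test,
    mean_sem,
    one_way_anova,
    pearson_r,
)


def functional_percent_summaries() -> dict[str, dict]:
    """Mean +/- SEM of the functional-genotype percentage per limb type:
    neck DNA at E16.5 (types I-III) and at E18.5 (type I)."""
    e165 = datasets.e165_embryos()
    e185 = datasets.e185_embryos()
    out: dict[str, dict] = {}
    for t in ("I", "II", "III"):
        vals = e165.loc[e165["type"] == t, "functional_percent_neck"].dropna()
        s = mean_sem(vals)
        out[f"E16.5 type {t}"] = {"n": s.n, "mean": s.mean, "sem": s.sem}
    vals = e185.loc[e185["type"] == "I", "functional_percent_neck"].dropna()
    s = mean_sem(vals)
    out["E18.5 type I"] = {"n": s.n, "mean": s.mean, "sem": s.sem}
    return out


def tubule_density_summaries() -> dict[str, dict]:
    """Mean +/- SEM of terminal-tubule density (per mm^2) per limb type at
    E16.5."""
    e165 = datasets.e165_embryos()
    out: dict[str, dict] = {}
    for t in ("I", "II", "III", "WT"):
        vals = e165.loc[e165["type"] == t, "tubule_density"].dropna()
        s = mean_sem(vals)
        out[t] = {"n": s.n, "mean": s.mean, "sem": s.sem}
    return out


def spc_correlations() -> dict[str, dict]:
    """Pearson correlations of SPC-positive percentage against functional
    genotype dose (neck and limb DNA) and against embryo weight, over the
    immunostained type III embryos at E18.5."""
    e185 = datasets.e185_embryos()
    stained = e185.dropna(subset=["spc_positive_percent"])
    spc = stained["spc_positive_percent"]
    out = {}
    for key, col in (
        ("neck", "functional_percent_neck"),
        ("limb", "functional_percent_limb"),
        ("weight", "weight_g"),
    ):
        res = pearson_r(stained[col], spc)
        out[key] = {"r": res.r, "n": res.n}
    return out


def functional_percent_anova() -> dict:
    """Omnibus one-way ANOVA over the three E16.5 functional-percentage
    groups."""
    e165 = datasets.e165_embryos()
    groups = [
        e165.loc[e165["type"] == t, "functional_percent_neck"].dropna().to_numpy()
        for t in ("I", "II", "III")
    ]
    res = one_way_anova(groups)
    return {"F": res.F, "df": (res.df_between, res.df_within), "p": res.p}


def tubule_density_dunnett(seed: int = 0, n_draws: int = 200_000) -> dict[str, dict]:
    """Dunnett's test of terminal-tubule density in types I-III against the
    wild-type control."""
    e165 = datasets.e165_embryos()
    control = e165.loc[e165["type"] == "WT", "tubule_density"].to_numpy()
    labels = ("I", "II", "III")
    treatments = [
        e165.loc[e165["type"] == t, "tubule_density"].to_numpy() for t in labels
    ]
    res = dunnett_test(control, treatments, seed=seed, n_draws=n_draws)
    return {
        t: {"t": res.t_statistics[i], "p_adjusted": res.adjusted_p[i],
            "significant": res.significant[i]}
        for i, t in enumerate(labels)
    }


def concordance_tests() -> pd.DataFrame:
    """Cross-tissue chi-square concordance test per embryo; rows where the
    table is degenerate (a genotype absent from every tissue) are reported
    as not applicable."""
    rows = []
    for embryo_id, table in datasets.tissue_read_counts().items():
        try:
            res = chi_square(table)
            rows.append(
                {
                    "embryo_id": embryo_id,
                    "statistic": res.statistic,
                    "df": res.df,
                    "p_value": res.p_value,
                    "p_reported": res.format_p(),
                    "min_expected": res.min_expected,
                    "applicable": res.applicable,
                }
            )
        except ValueError:
            rows.append(
                {
                    "embryo_id": embryo_id,
                    "statistic": np.nan,
                    "df": 0,
                    "p_value": np.nan,
                    "p_reported": "N.A.",
                    "min_expected": np.nan,
                    "applicable": False,
                }
            )
    return pd.DataFrame(rows)


def founder_study_summary(seed: int = 0) -> dict:
    """All headline statistics in one nested dict (used by the report CLI)."""
    return {
        "functional_percent": functional_percent_summaries(),
        "tubule_density": tubule_density_summaries(),
        "spc_correlations": spc_correlations(),
        "anova": functional_percent_anova(),
        "dunnett": tubule_density_dunnett(seed=seed),
        "concordance": concordance_tests().to_dict(orient="records"),
    }
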