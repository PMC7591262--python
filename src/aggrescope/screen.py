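"""Deletion-screen hit triage, phenotype categorization, and enrichment.

A deletion collection carrying inducible poison/antidote plasmids is spot
inoculated on inducing and non-inducing media and growth is scored on an
ordinal 0-4 scale.  Stage 1 flags strains that grow poorly on inducing
media with the toxin plasmids but normally without induction; stage 2
retests the flagged strains with empty vectors and rejects those that are
sick on inducing (galactose) media regardless of toxin expression.
Confirmed hits are categorized from imaging features (signal level,
dispersal of either protein) and categories are tested for enrichment with
Fisher's exact test and Benjamini-Hochberg FDR correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GROWTH_COLUMNS",
    "PHENOTYPES",
    "triage_stage1",
    "triage_stage2",
    "categorize_phenotypes",
    "enrichment",
]

GROWTH_COLUMNS = [
    "growth_wtf4_inducing",
    "growth_wtf4_noninducing",
    "growth_ev_inducing",
    "growth_ev_noninducing",
]

PHENOTYPES = [
    "dispersed_both",
    "antidote_normal_poison_dispersed",
    "low_signal",
    "wildtype_like",
    "unscored",
]

DEFAULT_FAIL_THRESHOLD = 1  # <= faint growth at the undiluted spot
DEFAULT_SIGNAL_FLOOR = 0.2


def _check_growth(records: pd.DataFrame) -> None:
    for col in GROWTH_COLUMNS:
        if col not in records.columns:
            raise ValueError(f"records lack growth column {col!r}")
        vals = records[col]
        if ((vals < 0) | (vals > 4)).any():
            raise ValueError(f"{col}: growth scores must be ordinal 0-4")


def triage_stage1(
    records: pd.DataFrame, fail_threshold: int = DEFAULT_FAIL_THRESHOLD
) -> pd.DataFrame:
    """Flag strains that grow poorly on inducing media with toxin plasmids.

    ``stage1_fail`` requires failure under induction AND normal growth
    without induction, so constitutively sick strains are not flagged.
    """
    _check_growth(records)
    out = records.copy()
    out["stage1_fail"] = (
        (out["growth_wtf4_inducing"] <= fail_threshold)
        & (out["growth_wtf4_noninducing"] > fail_threshold)
    )
    return out


def triage_stage2(
    records: pd.DataFrame, fail_threshold: int = DEFAULT_FAIL_THRESHOLD
) -> pd.DataFrame:
    """Confirm stage-1 strains that grow normally with empty vectors.

    A flagged strain that is also sick on inducing media with empty vectors
    fails for reasons independent of toxin expression and is rejected.
    """
    if "stage1_fail" not in records.columns:
        raise ValueError("run triage_stage1 first")
    out = records.copy()
    out["confirmed_hit"] = out["stage1_fail"] & (
        out["growth_ev_inducing"] > fail_threshold
    )
    return out


def categorize_phenotypes(
    records: pd.DataFrame,
    signal_floor: float = DEFAULT_SIGNAL_FLOOR,
) -> pd.DataFrame:
    """Assign each confirmed hit exactly one localization phenotype.

    Feature columns (per hit): ``signal_level`` (float), and booleans
    ``antidote_dispersed`` and ``poison_dispersed``.  Decision order:
    low_signal first (dispersal is unscorable without signal), then
    antidote-normal/poison-dispersed, then dispersed_both if either protein
    is dispersed, else wildtype_like.  Non-hits stay ``unscored``, so the
    scored categories always partition the confirmed hits.
    """
    if "confirmed_hit" not in records.columns:
        raise ValueError("run triage_stage2 first")
    out = records.copy()
    phen = np.full(len(out), "unscored", dtype=object)
    hits = out["confirmed_hit"].to_numpy(dtype=bool)
    low = out["signal_level"].to_numpy(dtype=float) < signal_floor
    anti_disp = out["antidote_dispersed"].to_numpy(dtype=bool)
    pois_disp = out["poison_dispersed"].to_numpy(dtype=bool)

    phen[hits & low] = "low_signal"
    sel = hits & ~low & pois_disp & ~anti_disp
    phen[sel] = "antidote_normal_poison_dispersed"
    sel = hits & ~low & (anti_disp | pois_disp) & (phen == "unscored")
    phen[sel] = "dispersed_both"
    phen[hits & (phen == "unscored")] = "wildtype_like"
    out["phenotype"] = phen
    return out


def enrichment(
    hit_categories: pd.Series | dict[str, str],
    background_categories: pd.Series | dict[str, str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Category enrichment of hits against the screened background.

    Inputs map strain -> category label; hits must be a subset of the
    background.  For each category a 2x2 table (hits in/out of category x
    background-non-hits in/out) is tested with two-sided Fisher's exact,
    and p-values are Benjamini-Hochberg corrected across categories.
    """
    hit_cat = pd.Series(hit_categories, dtype=object)
    bg_cat = pd.Series(background_categories, dtype=object)
    missing = set(hit_cat.index) - set(bg_cat.index)
    if missing:
        raise ValueError(f"hits not in background: {sorted(missing)[:5]}")
    n_hits = len(hit_cat)
    n_bg = len(bg_cat)
    rest = bg_cat.drop(index=hit_cat.index)

    rows = []
    for cat in sorted(bg_cat.unique()):
        a = int((hit_cat == cat).sum())  # hits in category
        b = n_hits - a  # hits outside
        c = int((rest == cat).sum())  # non-hit background in category
        d = (n_bg - n_hits) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "category": cat,
                "hit_count": a,
                "background_count": int((bg_cat == cat).sum()),
                "odds_ratio": float(odds) if np.isfinite(odds) else np.inf,
                "p": float(p),
            }
        )
    table = pd.DataFrame(rows)
    if len(table):
        _, q, _, _ = multipletests(table["p"].to_numpy(), method="fdr_bh")
        table["q"] = q
        table["significant"] = table["q"] < alpha
    return table
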