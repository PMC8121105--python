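"""Event classification and tests against the random-location null model.

Under the null, a diapedesis event lands on any monolayer pixel with equal
probability, so its category (TRI / BI / BODY, i.e. tricellular
paracellular / bicellular paracellular / transcellular) is multinomial
with probabilities equal to the categories' pixel frequencies.  Observed
category counts are tested with:

* a global Monte-Carlo exact multinomial goodness-of-fit test, ordered by
  outcome likelihood (small observed counts make asymptotic chi-square
  unreliable; it remains available for comparison), and
* per-category two-sided exact binomial tests with Benjamini-Hochberg
  adjustment, Wilson 95% intervals and enrichment ratios
  (observed fraction / null probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests
from statsmodels.stats.proportion import proportion_confint

from .frequency import (
    BI, BODY, CATEGORY_NAMES, OUTSIDE, TRI,
    CategoryMap, _assemble, _feature_distances, category_frequencies,
)
from .junctions import JunctionSet

__all__ = [
    "CategoryResult",
    "NullModelResult",
    "classify_events",
    "multinomial_gof",
    "chi_square_gof",
    "per_category_binomial",
    "run_null_analysis",
]

_CATEGORIES = ("TRI", "BI", "BODY")


@dataclass
class CategoryResult:
    category: str
    observed: int
    expected_prob: float
    p_value: float
    adjusted_p: float
    enrichment: float
    ci95: tuple[float, float]


@dataclass
class NullModelResult:
    """Null-model test results at one dilation radius."""

    radius: float
    observed: dict[str, int]           # counts for TRI, BI, BODY
    expected_probs: dict[str, float]
    global_p: float
    per_category: list[CategoryResult]
    n_events: int
    n_unclassifiable: int
    n_mc: int
    seed: int | None

    def to_dict(self) -> dict:
        d = asdict(self)
        for c in d["per_category"]:
            c["ci95"] = list(c["ci95"])
        return d

    def summary_row(self) -> dict:
        row = {
            "radius_um": self.radius,
            "n_events": self.n_events,
            "n_tri": self.observed["TRI"],
            "n_bi": self.observed["BI"],
            "n_body": self.observed["BODY"],
            "p_tri_null": self.expected_probs["TRI"],
            "p_bi_null": self.expected_probs["BI"],
            "p_body_null": self.expected_probs["BODY"],
            "global_p": self.global_p,
        }
        for c in self.per_category:
            key = c.category.lower()
            row[f"{key}_enrichment"] = c.enrichment
            row[f"{key}_adj_p"] = c.adjusted_p
        return row


def classify_events(events: pd.DataFrame, cmap: CategoryMap) -> pd.DataFrame:
    """Assign each event the category of its containing pixel.

    Events are snapped to the pixel containing their (x_um, y_um)
    coordinate.  Events outside the image bounds or on OUTSIDE pixels are
    flagged ``unclassifiable`` (with a reason) rather than dropped
    silently; they carry no category and are excluded from counts.
    Returns a copy with ``observed_category`` and ``unclassifiable``
    columns; row order is preserved and irrelevant to any count.
    """
    ps = cmap.pixel_size
    H, W = cmap.shape
    out = events.copy()
    cols = np.floor(out["x_um"].to_numpy() / ps).astype(int)
    rows = np.floor(out["y_um"].to_numpy() / ps).astype(int)
    in_bounds = (rows >= 0) & (rows < H) & (cols >= 0) & (cols < W)
    observed = np.full(len(out), "", dtype=object)
    reason = np.full(len(out), "", dtype=object)
    reason[~in_bounds] = "out_of_bounds"
    r_ok, c_ok = rows[in_bounds], cols[in_bounds]
    codes = cmap.categories[r_ok, c_ok]
    obs_ok = np.array([CATEGORY_NAMES[int(c)] for c in codes], dtype=object)
    obs_ok[codes == OUTSIDE] = ""
    observed[in_bounds] = obs_ok
    idx = np.where(in_bounds)[0][codes == OUTSIDE]
    reason[idx] = "outside_monolayer"
    out["observed_category"] = observed
    out["unclassifiable"] = reason
    return out


def _counts(classified: pd.DataFrame) -> dict[str, int]:
    ok = classified[classified["unclassifiable"] == ""]
    vc = ok["observed_category"].value_counts()
    return {c: int(vc.get(c, 0)) for c in _CATEGORIES}


def multinomial_gof(observed, probs, n_mc: int = 9999,
                    seed: int | None = None) -> float:
    """Monte-Carlo exact multinomial goodness-of-fit p-value.

    Simulates ``n_mc`` multinomial draws of the observed total under
    ``probs`` and counts draws at most as likely (by multinomial pmf) as
    the observed outcome:  p = (1 + #{logL_sim <= logL_obs}) / (n_mc + 1).
    The add-one form keeps p strictly positive; a category with null
    probability 0 but a nonzero observed count has likelihood 0 and is
    always rejected.  Deterministic for a fixed seed.
    """
    observed = np.asarray(observed, dtype=int)
    probs = np.asarray(probs, dtype=float)
    n = int(observed.sum())
    if n < 1:
        raise ValueError("need at least one classified event")
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("null probabilities must sum to 1")
    if n_mc < 999:
        raise ValueError("n_mc must be >= 999 for a usable p resolution")

    with np.errstate(divide="ignore", invalid="ignore"):
        logl_obs = stats.multinomial.logpmf(observed, n, probs)
    if np.isnan(logl_obs):
        logl_obs = -np.inf

    rng = np.random.default_rng(seed)
    sims = rng.multinomial(n, probs, size=n_mc)
    with np.errstate(divide="ignore", invalid="ignore"):
        logl_sim = stats.multinomial.logpmf(sims, n, probs)
    logl_sim = np.nan_to_num(logl_sim, nan=-np.inf)
    # tolerance keeps outcomes of equal likelihood counted as ties
    k = int((logl_sim <= logl_obs + 1e-9).sum())
    return (1 + k) / (n_mc + 1)


def chi_square_gof(observed, probs) -> float:
    """Asymptotic chi-square alternative to the Monte-Carlo test."""
    observed = np.asarray(observed, dtype=float)
    probs = np.asarray(probs, dtype=float)
    n = observed.sum()
    keep = probs > 0
    res = stats.chisquare(observed[keep], f_exp=n * probs[keep],
                          sum_check=False)
    return float(res.pvalue)


def per_category_binomial(observed, probs, alpha: float = 0.05
                          ) -> list[CategoryResult]:
    """Two-sided exact binomial test per category, BH-adjusted.

    For each category: exact binomial p of count k out of n at the null
    probability, Wilson 95% CI for the observed fraction, and enrichment
    k/n divided by the null probability (inf when the null probability is
    0 and k > 0).
    """
    observed = np.asarray(observed, dtype=int)
    probs = np.asarray(probs, dtype=float)
    n = int(observed.sum())
    if n < 1:
        raise ValueError("need at least one classified event")
    pvals, results = [], []
    for name, k, p0 in zip(_CATEGORIES, observed, probs):
        if p0 in (0.0, 1.0):
            p = 1.0 if k == int(n * p0) else 0.0
        else:
            p = stats.binomtest(int(k), n, p0, alternative="two-sided").pvalue
        lo, hi = proportion_confint(int(k), n, alpha=0.05, method="wilson")
        frac = k / n
        enrich = frac / p0 if p0 > 0 else (np.inf if k > 0 else 1.0)
        pvals.append(p)
        results.append(CategoryResult(
            category=name, observed=int(k), expected_prob=float(p0),
            p_value=float(p), adjusted_p=np.nan, enrichment=float(enrich),
            ci95=(float(lo), float(hi))))
    adj = multipletests(pvals, alpha=alpha, method="fdr_bh")[1]
    for r, a in zip(results, adj):
        r.adjusted_p = float(a)
    return results


def run_null_analysis(events: pd.DataFrame, j: JunctionSet,
                      radii, n_mc: int = 9999, seed: int | None = None,
                      denominator: str = "monolayer"
                      ) -> list[NullModelResult]:
    """Full null-model analysis over a radius sweep.

    For each radius: build the priority category map, take its pixel
    frequencies as null probabilities, classify the events, and run the
    global Monte-Carlo multinomial test plus the per-category binomial
    follow-up.  One independent MC seed is drawn per radius from ``seed``.
    """
    if len(events) == 0:
        raise ValueError("no events supplied")
    radii = sorted(float(r) for r in radii)
    d_tri, d_bi = _feature_distances(j)
    seeds = np.random.SeedSequence(seed).generate_state(len(radii)) % (2**31)
    results = []
    for r, mc_seed in zip(radii, seeds):
        cmap = _assemble(d_tri, d_bi, j.monolayer_mask, r, j.pixel_size)
        freqs = category_frequencies(cmap, denominator=denominator)
        classified = classify_events(events, cmap)
        counts = _counts(classified)
        obs = [counts[c] for c in _CATEGORIES]
        if sum(obs) == 0:
            raise ValueError(
                f"radius {r}: no classifiable events on the monolayer")
        global_p = multinomial_gof(obs, freqs.probs, n_mc=n_mc,
                                   seed=int(mc_seed))
        per_cat = per_category_binomial(obs, freqs.probs)
        results.append(NullModelResult(
            radius=r,
            observed=counts,
            expected_probs=dict(zip(_CATEGORIES, freqs.probs)),
            global_p=global_p,
            per_category=per_cat,
            n_events=int(sum(obs)),
            n_unclassifiable=int((classified["unclassifiable"] != "").sum()),
            n_mc=n_mc,
            seed=seed,
        ))
    return results
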