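"""Ecological indices for soil nematode communities.

Diversity indices (Shannon H', Pielou J', Simpson dominance lambda) work on
raw genus counts.  The decomposition-channel, food-web-maturity and
faunal-profile indices (NCR, WI, MI, PPI, EI, SI) work on a
:class:`~nemafauna.community.GuildCpTally`.

Two formula dialects are supported for the faunal-profile components and PPI:

``canonical``
    The standard faunal-profile framework: the basal component is built from
    c-p 2 bacterivores and fungivores, b = 0.8*(Ba2 + Fu2); the enrichment
    component from opportunistic bacterivores, e = 3.2*Ba1 + 0.8*Fu2; PPI is
    normalized within the plant-parasite guild, keeping it on the 1-5 c-p
    scale.

``paper_literal``
    Substitutes plant-parasite classes in b and e (b = 0.8*(Pp2 + Fu2),
    e = 3.2*Pp1 + 0.8*Fu2) and normalizes PPI by the whole community, as some
    method sections print the formulas.  Kept first-class so either reading
    can be reproduced.

Both dialects share the structure component
s = sum_{k=3..5} (Ba_k + Fu_k + Op_k) * W_k with W3 = 1.8, W4 = 3.2,
W5 = 5.0, and EI = 100*e/(e+b), SI = 100*s/(s+b).

Undefined values (e.g. WI with no plant parasites) raise
:class:`~nemafauna.errors.UndefinedIndexError`; :func:`index_table` converts
them into explicit NA markers with the reason recorded.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .community import CommunityMatrix, GuildCpTally, tally_guild_cp
from .errors import UndefinedIndexError, ValidationError
from .groupstats import compact_letters, lsd_pairwise, one_way_anova

FAUNAL_MODES = ("canonical", "paper_literal")
STRUCTURE_WEIGHTS = {3: 1.8, 4: 3.2, 5: 5.0}
FREE_LIVING_GUILDS = ("Ba", "Fu", "Op")

INDEX_NAMES = ("H_prime", "J_prime", "lambda_dom", "NCR", "WI",
               "MI", "PPI", "EI", "SI")


# ---------------------------------------------------------------- diversity

def _proportions(counts) -> np.ndarray:
    arr = np.asarray(list(counts), dtype=float)
    if arr.size and (arr < 0).any():
        raise ValidationError("counts must be non-negative")
    total = arr.sum()
    if total <= 0:
        raise UndefinedIndexError("diversity", "community is empty (N = 0)")
    return arr[arr > 0] / total


def shannon(counts) -> float:
    """Shannon-Wiener diversity H' = -sum p_i ln p_i over nonzero groups."""
    p = _proportions(counts)
    return float(-(p * np.log(p)).sum())


def pielou(counts) -> float:
    """Pielou evenness J' = H'/ln S, S = number of nonzero groups."""
    p = _proportions(counts)
    s = p.size
    if s < 2:
        raise UndefinedIndexError(
            "J_prime", "evenness needs at least 2 groups (ln S = 0)"
        )
    return float(-(p * np.log(p)).sum() / math.log(s))


def simpson_dominance(counts) -> float:
    """Simpson dominance lambda = sum p_i^2 (1 = single dominant group)."""
    p = _proportions(counts)
    return float((p ** 2).sum())


# ------------------------------------------------------- channel & maturity

def ncr(tally: GuildCpTally) -> float:
    """Nematode channel ratio Ba/(Ba+Fu); > 0.5 means bacterial channel."""
    ba, fu = tally.guild_total("Ba"), tally.guild_total("Fu")
    if ba + fu <= 0:
        raise UndefinedIndexError("NCR", "no microbial feeders (Ba + Fu = 0)")
    return ba / (ba + fu)


def wi(tally: GuildCpTally) -> float:
    """Wasilewska index (Ba+Fu)/Pp; high = mineralization channel active."""
    pp = tally.guild_total("Pp")
    if pp <= 0:
        raise UndefinedIndexError("WI", "no plant parasites (Pp = 0)")
    return (tally.guild_total("Ba") + tally.guild_total("Fu")) / pp


def maturity_index(tally: GuildCpTally) -> float:
    """MI: abundance-weighted mean c-p of free-living (non-Pp) nematodes."""
    free = sum(tally.guild_total(g) for g in FREE_LIVING_GUILDS)
    if free <= 0:
        raise UndefinedIndexError("MI", "no free-living individuals")
    weighted = sum(
        cp * v for (g, cp), v in tally.cells.items() if g in FREE_LIVING_GUILDS
    )
    return weighted / free


def ppi(tally: GuildCpTally, mode: str = "canonical") -> float:
    """Plant parasite index: weighted mean c-p of plant parasites.

    canonical: normalized within Pp (stays on the 1-5 scale);
    paper_literal: normalized by the whole community.
    """
    _check_mode(mode)
    pp = tally.guild_total("Pp")
    if pp <= 0:
        raise UndefinedIndexError("PPI", "no plant parasites (Pp = 0)")
    weighted = sum(cp * v for (g, cp), v in tally.cells.items() if g == "Pp")
    denom = pp if mode == "canonical" else tally.total
    return weighted / denom


# ----------------------------------------------------------- faunal profile

@dataclass(frozen=True)
class FaunalComponents:
    """Weighted basal (b), enrichment (e) and structure (s) components."""

    b: float
    e: float
    s: float
    mode: str


def _check_mode(mode: str) -> None:
    if mode not in FAUNAL_MODES:
        raise ValidationError(
            f"mode must be one of {FAUNAL_MODES}, got {mode!r}"
        )


def faunal_components(tally: GuildCpTally, mode: str = "canonical") -> FaunalComponents:
    """Compute b, e, s for the enrichment/structure faunal profile."""
    _check_mode(mode)
    fu2 = tally[("Fu", 2)]
    if mode == "canonical":
        b = 0.8 * (tally[("Ba", 2)] + fu2)
        e = 3.2 * tally[("Ba", 1)] + 0.8 * fu2
    else:
        b = 0.8 * (tally[("Pp", 2)] + fu2)
        e = 3.2 * tally[("Pp", 1)] + 0.8 * fu2
    s = sum(
        w * (tally[("Ba", k)] + tally[("Fu", k)] + tally[("Op", k)])
        for k, w in STRUCTURE_WEIGHTS.items()
    )
    return FaunalComponents(b=b, e=e, s=s, mode=mode)


def enrichment_index(fc: FaunalComponents) -> float:
    """EI = 100 e/(e+b): responsiveness to nutrient enrichment, 0-100."""
    if fc.e + fc.b <= 0:
        raise UndefinedIndexError("EI", "e + b = 0 (no enrichment or basal fauna)")
    # clamp one-ulp floating overshoot so the 0-100 contract is exact
    return min(100.0, max(0.0, 100.0 * fc.e / (fc.e + fc.b)))


def structure_index(fc: FaunalComponents) -> float:
    """SI = 100 s/(s+b): food-web connectance / chain length, 0-100."""
    if fc.s + fc.b <= 0:
        raise UndefinedIndexError("SI", "s + b = 0 (no structure or basal fauna)")
    return min(100.0, max(0.0, 100.0 * fc.s / (fc.s + fc.b)))


def faunal_profile_quadrant(ei: float, si: float) -> tuple[str, bool]:
    """Place a community in the EI/SI faunal-profile plane.

    Quadrants by the conventional 50/50 split: A = enriched/disturbed
    (EI > 50, SI <= 50), B = enriched/structured, C = structured/resource-
    limited, D = basal/depleted.  Returns ``(quadrant, on_boundary)``;
    values exactly on a boundary fall to the lower quadrant and are flagged.
    """
    for name, v in (("EI", ei), ("SI", si)):
        if v is None or (isinstance(v, float) and math.isnan(v)):
            raise UndefinedIndexError(name, "undefined faunal-profile coordinate")
    boundary = ei == 50.0 or si == 50.0
    if ei > 50.0:
        quadrant = "B" if si > 50.0 else "A"
    else:
        quadrant = "C" if si > 50.0 else "D"
    return quadrant, boundary


# -------------------------------------------------------------- full tables

def sample_indices(sample, taxonomy, mode: str = "canonical") -> dict:
    """All nine indices for one sample; undefined entries become (nan, reason)."""
    _check_mode(mode)
    tally = tally_guild_cp(sample, taxonomy, on_unresolved="carry")
    counts = [n for n in sample.counts.values() if n > 0]
    fc = faunal_components(tally, mode=mode)
    evaluators = {
        "H_prime": lambda: shannon(counts),
        "J_prime": lambda: pielou(counts),
        "lambda_dom": lambda: simpson_dominance(counts),
        "NCR": lambda: ncr(tally),
        "WI": lambda: wi(tally),
        "MI": lambda: maturity_index(tally),
        "PPI": lambda: ppi(tally, mode=mode),
        "EI": lambda: enrichment_index(fc),
        "SI": lambda: structure_index(fc),
    }
    values: dict[str, float] = {}
    reasons: dict[str, str] = {}
    for name, fn in evaluators.items():
        try:
            values[name] = float(fn())
        except UndefinedIndexError as exc:
            values[name] = float("nan")
            reasons[name] = exc.reason
    return {"values": values, "reasons": reasons}


@dataclass
class IndexTable:
    """Per-sample index values and per-treatment summaries.

    ``per_sample``: one row per sample with the nine index columns (NaN where
    undefined) plus ``<index>_reason`` columns explaining each NaN.
    ``per_treatment``: long table ``treatment,index,mean,se,letter,n_defined``.
    """

    per_sample: pd.DataFrame
    per_treatment: pd.DataFrame

    def write(self, per_sample_path, per_treatment_path) -> None:
        out = self.per_sample.copy()
        self.per_sample.to_csv(per_sample_path, index=False, na_rep="NA")
        self.per_treatment.to_csv(per_treatment_path, index=False, na_rep="NA")


def index_table(matrix: CommunityMatrix, mode: str = "canonical",
                alpha: float = 0.05) -> IndexTable:
    """Compute every index per sample, then mean +/- SE and significance
    letters per treatment.

    Aggregation is mean-of-replicates (each replicate's index computed first,
    then averaged), matching how replicated field studies tabulate indices.
    Undefined per-sample values are excluded from the mean; ``n_defined``
    records how many replicates contributed.  Letters come from one-way
    ANOVA + LSD at ``alpha`` on the defined values; treatments sharing a
    letter are not significantly different.
    """
    _check_mode(mode)
    if len(matrix) == 0:
        raise ValidationError("empty community matrix")

    rows = []
    for sample in matrix:
        res = sample_indices(sample, matrix.taxonomy, mode=mode)
        row = {
            "sample_id": sample.sample_id,
            "treatment": sample.treatment,
            "depth_layer": sample.depth_layer,
            "replicate": sample.replicate,
        }
        row.update(res["values"])
        for name in INDEX_NAMES:
            row[f"{name}_reason"] = res["reasons"].get(name, "")
        rows.append(row)
    per_sample = pd.DataFrame(rows)

    treatments = list(dict.fromkeys(per_sample["treatment"]))
    summary_rows = []
    for name in INDEX_NAMES:
        groups, labels = [], []
        for t in treatments:
            vals = per_sample.loc[per_sample["treatment"] == t, name].dropna()
            if len(vals):
                groups.append(vals.to_numpy())
                labels.append(t)
        letters = _letters_for(groups, labels, alpha)
        for t in treatments:
            vals = per_sample.loc[per_sample["treatment"] == t, name].dropna()
            n = len(vals)
            mean = float(vals.mean()) if n else float("nan")
            if n > 1:
                # identical replicates get SE exactly 0 (mean rounding would
                # otherwise leave ~1e-17 noise)
                se = 0.0 if vals.nunique() == 1 else float(
                    vals.std(ddof=1) / math.sqrt(n))
            else:
                se = float("nan")
            summary_rows.append({
                "treatment": t, "index": name,
                "mean": mean, "se": se,
                "letter": letters.get(t, ""),
                "n_defined": n,
            })
    per_treatment = pd.DataFrame(
        summary_rows,
        columns=["treatment", "index", "mean", "se", "letter", "n_defined"],
    )
    return IndexTable(per_sample=per_sample, per_treatment=per_treatment)


def _letters_for(groups, labels, alpha) -> dict[str, str]:
    """LSD compact letters; degenerate designs collapse to a single letter."""
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        return {lab: "a" for lab in labels}
    total_n = sum(len(g) for g in groups)
    if total_n <= len(groups):  # no residual df
        return {lab: "a" for lab in labels}
    means = {lab: float(np.mean(g)) for lab, g in zip(labels, groups)}
    anova = one_way_anova(groups)
    if anova.rows[1].ms == 0:  # zero within-group variance
        sig = {
            (labels[i], labels[j])
            for i in range(len(labels)) for j in range(i + 1, len(labels))
            if means[labels[i]] != means[labels[j]]
        }
    else:
        pairs = lsd_pairwise(groups, alpha=alpha, labels=labels)
        sig = {pair for pair, significant in pairs.items() if significant}
    return compact_letters(means, sig)
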