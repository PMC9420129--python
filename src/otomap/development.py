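"""Developmental-sequence proxies and class-weighted input composition.

The circuit's developmental order is carried by anatomical proxies:
hair-cell maturity class (from ciliary lengths), ribbon-synapse counts,
afferent myelination, and soma position in the ganglion. This module
quantifies the composition of each afferent's input by hair-cell class,
propagates those fractions onto central pathways (weighting each central
contact by its afferent's fractions), and runs the associated group
statistics (rank-sum, ANOVA, chi-squared).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ConnectivityTable, MissingInputError, ValidationError

CLASSES = ("striolar", "extrastriolar", "immature")

#: target groups counted in the divergence cross-tab; the two escape
#: populations (ipsilateral Mauthner + commissural escape neurons) are
#: pooled by default
DEFAULT_TARGET_GROUPS = {
    "mauthner": "escape",
    "commissural_escape": "escape",
    "svn": "svn",
    "tangential": "tangential",
    "vs": "vs",
    "vs_med": "vs",
    "vs_vent": "vs",
}


@dataclass(frozen=True)
class ClassFractions:
    """Fraction of input from each hair-cell class; sums to 1."""

    striolar: float
    extrastriolar: float
    immature: float
    basis: str  # "ribbon_weighted" | "distinct_cells"

    def as_array(self) -> np.ndarray:
        return np.array([self.striolar, self.extrastriolar, self.immature])


def afferent_class_fractions(
    aff_id: str,
    connectivity: ConnectivityTable,
    hc_classes: dict[str, str],
    basis: str = "ribbon_weighted",
) -> ClassFractions:
    """Input composition of one afferent by hair-cell maturity class.

    ``ribbon_weighted`` counts ribbon contacts; ``distinct_cells`` counts
    distinct presynaptic hair cells. The two coincide exactly when every
    contact count is 1.
    """
    if basis not in ("ribbon_weighted", "distinct_cells"):
        raise ValidationError(f"unknown basis {basis!r}")
    grp = connectivity.by_post(aff_id, kind="ribbon")
    if len(grp) == 0:
        raise MissingInputError(f"afferent {aff_id}: no ribbon inputs")
    totals = dict.fromkeys(CLASSES, 0.0)
    for _, row in grp.iterrows():
        cls = hc_classes.get(row["pre_id"])
        if cls not in CLASSES:
            raise ValidationError(
                f"hair cell {row['pre_id']}: missing or invalid class {cls!r}"
            )
        totals[cls] += float(row["count"]) if basis == "ribbon_weighted" else 1.0
    total = sum(totals.values())
    return ClassFractions(
        striolar=totals["striolar"] / total,
        extrastriolar=totals["extrastriolar"] / total,
        immature=totals["immature"] / total,
        basis=basis,
    )


def all_afferent_fractions(
    connectivity: ConnectivityTable, hc_classes: dict[str, str], basis: str = "ribbon_weighted"
) -> dict[str, ClassFractions]:
    out = {}
    for aff_id in connectivity.aggregated.query("kind == 'ribbon'")["post_id"].unique():
        out[aff_id] = afferent_class_fractions(aff_id, connectivity, hc_classes, basis)
    return out


@dataclass(frozen=True)
class PathwayComposition:
    """Class composition of a central pathway's utricular input."""

    population: str
    striolar: float
    extrastriolar: float
    immature: float
    myelinated_fraction: float
    n_neurons: int
    n_contacts: int


def pathway_composition(
    population: str,
    neuron_ids,
    connectivity: ConnectivityTable,
    afferent_fractions: dict[str, ClassFractions],
    myelin_flags: dict[str, bool] | None = None,
    myelin_basis: str = "contacts",
) -> PathwayComposition:
    """Contact-weighted input composition of a central population.

    Each central synaptic contact contributes its afferent's class
    fractions, weighted by the contact count; the myelinated fraction is
    the share of contacts (or, with ``myelin_basis='distinct_afferents'``,
    of distinct afferents) arising from myelinated afferents.
    """
    neuron_ids = {str(n) for n in neuron_ids}
    central = connectivity.aggregated.query("kind == 'central'")
    grp = central[central["post_id"].isin(neuron_ids)]
    if len(grp) == 0:
        raise MissingInputError(f"population {population}: no central contacts")
    missing = sorted(
        set(grp["pre_id"]) - set(afferent_fractions)
    )
    if missing:
        raise MissingInputError(
            f"population {population}: contributing afferent(s) lacking class "
            f"fractions: {missing}"
        )
    w = grp["count"].to_numpy(dtype=float)
    F = np.stack([afferent_fractions[a].as_array() for a in grp["pre_id"]])
    comp = (F * w[:, None]).sum(axis=0) / w.sum()
    myel_frac = np.nan
    if myelin_flags is not None:
        flags = np.array([bool(myelin_flags.get(a, False)) for a in grp["pre_id"]])
        if myelin_basis == "contacts":
            myel_frac = float(w[flags].sum() / w.sum())
        elif myelin_basis == "distinct_afferents":
            affs = grp["pre_id"].unique()
            myel_frac = float(
                np.mean([bool(myelin_flags.get(a, False)) for a in affs])
            )
        else:
            raise ValidationError(f"unknown myelin basis {myelin_basis!r}")
    return PathwayComposition(
        population=population,
        striolar=float(comp[0]),
        extrastriolar=float(comp[1]),
        immature=float(comp[2]),
        myelinated_fraction=myel_frac,
        n_neurons=len(neuron_ids & set(grp["post_id"])),
        n_contacts=int(w.sum()),
    )


def myelination_position_summary(afferents: pd.DataFrame) -> dict:
    """Soma mediolateral position of myelinated vs unmyelinated afferents.

    ``afferents`` needs columns ``ml`` and boolean ``myelinated``. Returns
    per-group median/IQR plus a two-sided Wilcoxon–Mann–Whitney test (exact
    below 25 per group when tie-free, normal approximation otherwise). With
    only one group populated, the test is skipped.
    """
    out: dict = {"groups": {}}
    groups = {}
    for name, flag in (("myelinated", True), ("unmyelinated", False)):
        vals = afferents.loc[afferents["myelinated"] == flag, "ml"].to_numpy(dtype=float)
        if vals.size:
            groups[name] = vals
            out["groups"][name] = {
                "n": int(vals.size),
                "median": float(np.median(vals)),
                "q25": float(np.percentile(vals, 25)),
                "q75": float(np.percentile(vals, 75)),
            }
    if len(groups) < 2:
        out["test"] = None
        return out
    x, y = groups["myelinated"], groups["unmyelinated"]
    method = (
        "exact"
        if (x.size < 25 and y.size < 25 and np.unique(np.concatenate([x, y])).size == x.size + y.size)
        else "asymptotic"
    )
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    out["test"] = {
        "name": "wilcoxon-mann-whitney",
        "statistic": float(res.statistic),
        "p": float(res.pvalue),
        "method": method,
    }
    return out


def divergence_counts(
    connectivity: ConnectivityTable,
    populations: dict[str, str],
    myelin_flags: dict[str, bool] | None = None,
    target_groups: dict[str, str] | None = None,
):
    """Per-afferent count of distinct central target groups, cross-tabbed
    by myelination.

    ``populations`` maps central neuron id -> population label; target
    groups default to {escape (Mauthner + commissural pooled), svn,
    tangential, vs}, giving a divergence count in 0..4.
    Returns ``(per_afferent, crosstab)``.
    """
    groups = target_groups or DEFAULT_TARGET_GROUPS
    central = connectivity.aggregated.query("kind == 'central'")
    unlabeled = sorted(set(central["post_id"]) - set(populations))
    if unlabeled:
        raise ValidationError(f"unlabeled central target(s): {unlabeled}")
    rows = []
    for aff_id, grp in central.groupby("pre_id"):
        targets = {
            groups[populations[t]]
            for t in grp["post_id"]
            if populations[t] in groups
        }
        rows.append(
            {
                "afferent": aff_id,
                "divergence": len(targets),
                "targets": ",".join(sorted(targets)),
                "myelinated": bool(myelin_flags.get(aff_id, False))
                if myelin_flags
                else None,
            }
        )
    per_afferent = pd.DataFrame(rows)
    crosstab = None
    if myelin_flags is not None and len(per_afferent):
        crosstab = pd.crosstab(per_afferent["myelinated"], per_afferent["divergence"])
    return per_afferent, crosstab


def ribbon_count_by_class(
    hc_table: pd.DataFrame, bonferroni: bool = False
) -> dict:
    """Ribbon-count distributions per maturity class with omnibus and
    pairwise tests.

    ``hc_table`` needs columns ``maturity`` and ``ribbon_count``. Runs a
    one-way ANOVA across populated classes then pairwise two-sided
    rank-sum tests (optionally Bonferroni-adjusted). Classes with no cells
    are excluded with a warning.
    """
    samples: dict[str, np.ndarray] = {}
    for cls in CLASSES:
        vals = hc_table.loc[hc_table["maturity"] == cls, "ribbon_count"].to_numpy(
            dtype=float
        )
        if vals.size == 0:
            warnings.warn(f"class {cls!r} has no cells; excluded", stacklevel=2)
            continue
        samples[cls] = vals
    if len(samples) < 2:
        raise ValidationError("need at least two populated classes")
    out: dict = {"per_class": {}, "pairwise": {}}
    for cls, vals in samples.items():
        out["per_class"][cls] = {
            "n": int(vals.size),
            "median": float(np.median(vals)),
            "q25": float(np.percentile(vals, 25)),
            "q75": float(np.percentile(vals, 75)),
        }
    if all(np.ptp(v) == 0 for v in samples.values()) and (
        len({v[0] for v in samples.values()}) == 1
    ):
        out["anova"] = {"p": 1.0, "flag": "undefined-variance"}
    else:
        f, p = stats.f_oneway(*samples.values())
        out["anova"] = {"F": float(f), "p": float(p)}
    pairs = [(a, b) for i, a in enumerate(samples) for b in list(samples)[i + 1 :]]
    for a, b in pairs:
        res = stats.mannwhitneyu(samples[a], samples[b], alternative="two-sided")
        p = float(res.pvalue)
        if bonferroni:
            p = min(1.0, p * len(pairs))
        out["pairwise"][f"{a}-{b}"] = {"statistic": float(res.statistic), "p": p}
    return out
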