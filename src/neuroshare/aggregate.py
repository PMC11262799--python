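"""Cross-frequency channel selectivity and region-level population prevalence.

Both summaries consume long-format category tables (one row per patient x
channel x band [x direction]) as produced by the taxonomy stages.

Cross-frequency selectivity asks how much of the selectivity seen in one
band survives once the other frequency bands are inspected: starting from
the channels selective to a domain in one band, each further band in turn
*deducts* every channel showing any significant response to the other
domain there (shared, preferred or other-domain-selective, either
direction).  The resulting trace of percentages is necessarily
non-increasing.

Population prevalence asks whether any anatomical region is selective at
the patient level: a region enters the table when at least two patients
have at least two significantly responsive channels in it, and a patient
counts as selective only when *all* their significant channels in the
region are selective for the same domain; any mixture, or any shared
channel, makes the patient's regional profile shared.  Preferred-category
channels are excluded before this analysis.
"""

from __future__ import annotations

import warnings

import pandas as pd

from .spectral import DEFAULT_BANDS

__all__ = ["cross_frequency_selectivity", "population_prevalence", "default_band_order"]

_RESPONSIVE = {"shared", "inconsistent", "preferred_speech", "preferred_music",
               "selective_speech", "selective_music"}


def default_band_order(start_band: str, bands=None) -> list[str]:
    """Ascending-frequency order starting at ``start_band``, wrapping."""
    names = list(bands) if bands is not None else list(DEFAULT_BANDS.names)
    if start_band not in names:
        raise ValueError(f"start band {start_band!r} not in scheme")
    i = names.index(start_band)
    return names[i:] + names[:i]


def _other_domain(domain: str) -> str:
    return {"speech": "music", "music": "speech"}[domain]


def _responsive_to(categories: set, domain: str) -> bool:
    """Does any of the channel's categories imply a significant response to
    ``domain``?  Shared/preferred/inconsistent respond to both domains;
    selective responds to its own domain only."""
    for cat in categories:
        if cat in ("shared", "inconsistent", "preferred_speech", "preferred_music"):
            return True
        if cat == f"selective_{domain}":
            return True
    return False


def cross_frequency_selectivity(
    categories: pd.DataFrame,
    domain: str,
    start_band: str,
    band_order: list[str] | None = None,
    total_channels: int | None = None,
) -> pd.DataFrame:
    """Deduction trace of exclusive selectivity for one domain.

    Parameters
    ----------
    categories : DataFrame
        Long format with columns ``patient, channel, band, category`` (a
        ``direction`` column, if present, is pooled: activation and
        deactivation responses both count).
    domain : {"speech", "music"}
    start_band : str
        Band whose selective channels seed the trace.
    band_order : list of str, optional
        Deduction order; must begin with ``start_band``.  Defaults to
        ascending frequency with wrap-around.
    total_channels : int, optional
        Denominator for the percentages; defaults to the number of distinct
        (patient, channel) pairs in ``categories``.

    Returns
    -------
    DataFrame with columns ``band`` (the band just deducted; first row is
    the start band itself), ``n_remaining``, ``percent``.
    """
    if band_order is None:
        band_order = default_band_order(start_band, categories["band"].unique().tolist()
                                        if start_band not in DEFAULT_BANDS.names
                                        else None)
    if band_order[0] != start_band:
        raise ValueError("band_order must begin with start_band")
    missing = set(band_order) - set(categories["band"].unique())
    if missing:
        raise ValueError(f"categories missing bands {sorted(missing)}")

    df = categories.copy()
    df["uid"] = list(zip(df["patient"], df["channel"]))
    total = total_channels if total_channels is not None else df["uid"].nunique()
    other = _other_domain(domain)

    # categories per channel per band (pooled over direction)
    by_band = {
        band: g.groupby("uid")["category"].agg(lambda s: set(map(str, s)))
        for band, g in df.groupby("band")
    }

    start = {
        uid
        for uid, cats in by_band[start_band].items()
        if f"selective_{domain}" in cats
    }
    rows = [{"band": start_band, "n_remaining": len(start),
             "percent": 100.0 * len(start) / max(total, 1)}]
    surviving = set(start)
    for band in band_order[1:]:
        cats = by_band[band]
        surviving = {
            uid
            for uid in surviving
            if not _responsive_to(cats.get(uid, set()), other)
        }
        rows.append({"band": band, "n_remaining": len(surviving),
                     "percent": 100.0 * len(surviving) / max(total, 1)})
    return pd.DataFrame(rows)


def _collapse_directions(group: pd.Series) -> str | None:
    """Collapse a channel's per-direction categories into one label.

    Significant in either direction counts; the selectivity label must
    agree across directions to stay selective, otherwise the channel is
    shared.  Returns None for a channel with no significant response.
    """
    cats = {str(c) for c in group if str(c) != "none"}
    if not cats:
        return None
    if cats == {"selective_speech"}:
        return "selective_speech"
    if cats == {"selective_music"}:
        return "selective_music"
    if cats <= {"preferred_speech"} or cats <= {"preferred_music"}:
        return cats.pop()
    if any(c.startswith("preferred") for c in cats):
        return "preferred_mixed"
    return "shared"


def population_prevalence(
    categories: pd.DataFrame,
    min_patients: int = 2,
    min_channels: int = 2,
) -> pd.DataFrame:
    """Per region x band patient-level prevalence of selective vs shared.

    ``categories`` needs columns ``patient, channel, region, band,
    category`` (optional ``direction`` is collapsed first).  Channels whose
    collapsed label is preferred are excluded before anything else.

    Returns a DataFrame with one row per retained region x band:
    ``n_patients`` (explored patients meeting the >= min_channels rule),
    counts and percentages of patients labeled selective_speech,
    selective_music and shared (percentages sum to 100).
    """
    df = categories.copy()
    keys = ["patient", "channel", "region", "band"]
    collapsed = (
        df.groupby(keys, observed=True)["category"]
        .agg(_collapse_directions)
        .dropna()
        .reset_index(name="label")
    )
    collapsed = collapsed[~collapsed["label"].str.startswith("preferred")]

    rows = []
    for (region, band), g in collapsed.groupby(["region", "band"], observed=True):
        per_patient = g.groupby("patient")["label"].agg(list)
        per_patient = per_patient[per_patient.map(len) >= min_channels]
        if len(per_patient) < min_patients:
            continue
        counts = {"selective_speech": 0, "selective_music": 0, "shared": 0}
        for labels in per_patient:
            uniq = set(labels)
            if uniq == {"selective_speech"}:
                counts["selective_speech"] += 1
            elif uniq == {"selective_music"}:
                counts["selective_music"] += 1
            else:
                counts["shared"] += 1
        n = len(per_patient)
        rows.append(
            {
                "region": region,
                "band": band,
                "n_patients": n,
                "n_selective_speech": counts["selective_speech"],
                "n_selective_music": counts["selective_music"],
                "n_shared": counts["shared"],
                "pct_selective_speech": 100.0 * counts["selective_speech"] / n,
                "pct_selective_music": 100.0 * counts["selective_music"] / n,
                "pct_shared": 100.0 * counts["shared"] / n,
            }
        )
    if not rows:
        warnings.warn("no region meets the inclusion rule", RuntimeWarning,
                      stacklevel=2)
        return pd.DataFrame(
            columns=[
                "region", "band", "n_patients", "n_selective_speech",
                "n_selective_music", "n_shared", "pct_selective_speech",
                "pct_selective_music", "pct_shared",
            ]
        )
    return pd.DataFrame(rows).sort_values(["region", "band"]).reset_index(drop=True)
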