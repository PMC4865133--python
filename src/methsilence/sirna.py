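"""24-nt siRNA quantification, RPTM normalization, polymerase dependence calls.

Abundance is normalized as reads per ten million (RPTM): count x 10^7 divided
by the total reads of the small-RNA library. Dependence on Pol IV / Pol V is
read off the fold change of mutant RPTM (nrpd1 / nrpe1) over wild type: a
fold change below the cutoff (default 0.5) means the siRNA class depends on
that polymerase. Features with wild-type abundance under a floor (default
5 RPTM) are uninformative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import pandas as pd

RPTM_SCALE = 10_000_000


def count_24nt_reads(length_counts: Mapping, feature_id: str | None = None) -> int:
    """Select the 24-nt stratum from a per-length count mapping (keys may be
    int or str)."""
    for key in (24, "24"):
        if key in length_counts:
            return int(length_counts[key])
    where = f" for {feature_id}" if feature_id else ""
    raise KeyError(f"no 24-nt stratum in length counts{where}")


def rptm(count: int, library_total: int) -> float:
    """Reads per ten million: count x 10^7 / library_total."""
    if library_total <= 0:
        raise ValueError(f"library_total must be positive, got {library_total}")
    return count * RPTM_SCALE / library_total


def dependence_fold_change(rptm_wt: float, rptm_mut: float, pseudocount: float = 1.0) -> float:
    """(mutant + c) / (wild type + c) on the RPTM scale."""
    return (rptm_mut + pseudocount) / (rptm_wt + pseudocount)


@dataclass(frozen=True, slots=True)
class SmallRNAProfile:
    feature_id: str
    rptm: dict  # genotype -> RPTM
    fold_change: dict  # mutant genotype -> fold vs wild type
    pol_iv: str  # "Pol IV-dependent" | "Pol IV-independent" | "uninformative"
    pol_v: str


def classify_dependence(
    fold_nrpd1: float, fold_nrpe1: float, rptm_wt: float,
    cutoff: float = 0.5, min_wt_rptm: float = 5.0,
) -> tuple[str, str]:
    if rptm_wt < min_wt_rptm:
        return "uninformative", "uninformative"
    pol_iv = "Pol IV-dependent" if fold_nrpd1 < cutoff else "Pol IV-independent"
    pol_v = "Pol V-dependent" if fold_nrpe1 < cutoff else "Pol V-independent"
    return pol_iv, pol_v


def profile_features(
    counts_24nt: Mapping[str, Mapping[str, int]],
    library_totals: Mapping[str, int],
    wt: str = "WT",
    pol_iv_mutant: str = "nrpd1",
    pol_v_mutant: str = "nrpe1",
    pseudocount: float = 1.0,
    cutoff: float = 0.5,
    min_wt_rptm: float = 5.0,
) -> list[SmallRNAProfile]:
    """Build per-feature RPTM profiles and dependence calls.

    ``counts_24nt`` maps genotype -> {feature_id: 24-nt count}; every genotype
    needs a library total. Output is ordered by feature id.
    """
    genotypes = sorted(counts_24nt)
    for g in (wt, pol_iv_mutant, pol_v_mutant):
        if g not in counts_24nt:
            raise ValueError(f"genotype {g!r} missing from counts")
    feature_ids = sorted(counts_24nt[wt])
    profiles = []
    for fid in feature_ids:
        r = {g: rptm(counts_24nt[g][fid], library_totals[g]) for g in genotypes}
        fc = {
            g: dependence_fold_change(r[wt], r[g], pseudocount)
            for g in genotypes
            if g != wt
        }
        pol_iv, pol_v = classify_dependence(
            fc[pol_iv_mutant], fc[pol_v_mutant], r[wt], cutoff, min_wt_rptm
        )
        profiles.append(SmallRNAProfile(fid, r, fc, pol_iv, pol_v))
    return profiles


def profiles_to_frame(profiles) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {"feature_id": p.feature_id, "pol_iv": p.pol_iv, "pol_v": p.pol_v}
        row.update({f"rptm_{g}": v for g, v in sorted(p.rptm.items())})
        row.update({f"fold_{g}": v for g, v in sorted(p.fold_change.items())})
        rows.append(row)
    return pd.DataFrame(rows)
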