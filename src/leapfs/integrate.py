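"""Integration of structure-based and text-based predictions.

Residue-wise overlap statistics between predicted sites and annotated
sites, enrichment ratios, and the combined per-residue report table
(one row per (site, residue) pair with annotation flags).

Overlap statistics: for an NSM site with residue set R_NSM and the
union R_DPA of all predicted residues in the structure, the site's
recall is |R_NSM & R_DPA| / |R_NSM|.  For a predicted site R_DPA and a
reference set (all NSM residues, or only NSM-valid residues) the site's
precision is |R_DPA & R_ref| / |R_DPA|.  Threshold curves report the
fraction of sites whose metric is >= t over a grid of thresholds.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dpa import DPASite
from .structure_io import DomainStructure, NSMSite, ResidueKey

REPORT_COLUMNS = [
    "DPA_CLUSTER_ID", "ENTITY_ID", "CHAIN_ID", "RES_SEQ_NUM", "ICODE",
    "RES_NAME", "IS_LIT_MATCH", "IS_CSA_LIT", "IS_NSM_VALID", "IS_NSM",
    "IS_CURATED_FAMILY", "IS_NSM_FAMILY", "NSM_HETERO_CODES",
]

DEFAULT_THRESHOLDS = tuple(round(0.1 * k, 1) for k in range(1, 11))


def site_recall(nsm_site_residues: set, all_dpa_residues: set) -> float:
    """Fraction of an annotated site's residues covered by predictions."""
    if not nsm_site_residues:
        raise ValueError("empty NSM site")
    return len(set(nsm_site_residues) & set(all_dpa_residues)) / len(set(nsm_site_residues))


def site_precision(dpa_site_residues: set, reference_residues: set) -> float:
    """Fraction of a predicted site's residues found in the reference."""
    if not dpa_site_residues:
        raise ValueError("empty predicted site")
    return len(set(dpa_site_residues) & set(reference_residues)) / len(set(dpa_site_residues))


def sites_overlap(site_a: Iterable, site_b: Iterable) -> bool:
    """Site matching: nonempty residue-set intersection."""
    return bool(set(site_a) & set(site_b))


def threshold_curve(
    values: Sequence[float],
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
) -> list[tuple[float, float]]:
    """(t, fraction of values >= t) pairs; nonincreasing in t."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("no values")
    return [(float(t), float(np.mean(v >= t))) for t in thresholds]


def enrichment(
    n_hit_a: int, n_a: int,
    n_hit_b: int, n_b: int,
    rounding: str = "paper",
) -> float:
    """Fold-enrichment of rate A over rate B.

    ``rounding="paper"`` rounds each rate to a whole percent before
    dividing (the convention used for printed worked examples);
    ``"exact"`` divides the raw fractions.  Returns NaN when the
    denominator rate rounds to (or is) zero.
    """
    if n_a <= 0 or n_b <= 0:
        raise ValueError("population sizes must be positive")
    if rounding == "paper":
        pct_a = round(100.0 * n_hit_a / n_a)
        pct_b = round(100.0 * n_hit_b / n_b)
        if pct_b == 0:
            return math.nan
        return pct_a / pct_b
    if rounding == "exact":
        rate_b = n_hit_b / n_b
        if rate_b == 0:
            return math.nan
        return (n_hit_a / n_a) / rate_b
    raise ValueError(f"unknown rounding mode {rounding!r}")


def build_report(
    domain: DomainStructure,
    sites: Sequence[DPASite],
    nsm_sites: Sequence[NSMSite] = (),
    text_residues: set[ResidueKey] | frozenset = frozenset(),
    csa_residues: set[ResidueKey] | frozenset = frozenset(),
    family_curated: set[ResidueKey] | frozenset = frozenset(),
    family_nsm: set[ResidueKey] | frozenset = frozenset(),
) -> pd.DataFrame:
    """Per-residue report: one row per (predicted site, residue).

    Residues appearing in several sites get one row per site.  Flags:
    IS_LIT_MATCH (residue matches a grounded text residue), IS_CSA_LIT,
    IS_NSM_VALID / IS_NSM (near a MOAD-valid / any small molecule),
    IS_CURATED_FAMILY and IS_NSM_FAMILY (family-aligned curated / NSM
    annotation).  NSM_HETERO_CODES lists nearby molecules' hetero codes
    with their curation status in parentheses, comma-delimited.
    """
    domain_keys = set(domain.index)
    offenders = []
    for name, keys in [("text", text_residues), ("csa", csa_residues),
                       ("family_curated", family_curated), ("family_nsm", family_nsm)]:
        bad = set(keys) - domain_keys
        if bad:
            offenders.append(f"{name}: {sorted(bad)}")
    for s in nsm_sites:
        bad = set(s.residues) - domain_keys
        if bad:
            offenders.append(f"nsm site {s.site_id}: {sorted(bad)}")
    if offenders:
        raise KeyError("annotation keys not present in domain — " + "; ".join(offenders))

    nsm_any: set[ResidueKey] = set()
    nsm_valid: set[ResidueKey] = set()
    codes_of: dict[ResidueKey, list[str]] = {}
    for s in nsm_sites:
        label = "-".join(s.molecule)
        if s.validity in ("valid", "invalid"):
            label += f"({s.validity})"
        for key in s.residues:
            nsm_any.add(key)
            if s.validity == "valid":
                nsm_valid.add(key)
            codes_of.setdefault(key, []).append(label)

    rows = []
    for site in sites:
        cluster_id = f"{domain.domain_id}.{site.site_label}"
        for key in sorted(site.residues):
            rec = domain.index[key]
            rows.append({
                "DPA_CLUSTER_ID": cluster_id,
                "ENTITY_ID": rec.entity_id,
                "CHAIN_ID": rec.chain_id,
                "RES_SEQ_NUM": rec.auth_seq_num,
                "ICODE": rec.icode,
                "RES_NAME": rec.comp_id,
                "IS_LIT_MATCH": int(key in text_residues),
                "IS_CSA_LIT": int(key in csa_residues),
                "IS_NSM_VALID": int(key in nsm_valid),
                "IS_NSM": int(key in nsm_any),
                "IS_CURATED_FAMILY": int(key in family_curated
                                         or key in nsm_valid or key in csa_residues),
                "IS_NSM_FAMILY": int(key in family_nsm or key in nsm_any),
                "NSM_HETERO_CODES": ",".join(sorted(codes_of.get(key, []))),
            })
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


def write_report(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)
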