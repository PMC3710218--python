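"""Join eQTL results with annotation catalogs and orient effect directions.

An eQTL's slope is reported per alt-allele copy. Published associations
report a risk allele; the direction of effect per risk-allele copy is the
slope's sign when the risk allele is the alt allele and the flipped sign
when it is the ref allele. A risk allele matching neither allele leaves the
direction absent (logged).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .core import ValidationError
from .enrichment import EnrichmentResult, NullSetCollection, overlap_enrichment

logger = logging.getLogger(__name__)

ANNOTATED_COLUMNS = [
    "snp_id", "annotation", "evidence_level", "mirna_id", "p", "beta_alt",
    "direction_risk",
]


def annotate_eqtls(
    eqtls: pd.DataFrame,
    catalog: pd.DataFrame,
    snps: pd.DataFrame,
    p_max: float = 1e-4,
) -> pd.DataFrame:
    """Inner-join eQTL records below ``p_max`` with catalog annotations.

    ``snps`` supplies ref/alt alleles (indexed by snp_id). ``direction_risk``
    is +1/-1 per risk-allele copy, or NA when the risk allele is unknown or
    matches neither allele.
    """
    hits = eqtls[eqtls["p"] < p_max]
    merged = hits.merge(catalog, left_on="x_id", right_on="snp_id", how="inner")
    if merged.empty:
        return pd.DataFrame(columns=ANNOTATED_COLUMNS)
    alleles = snps[["ref_allele", "alt_allele"]]
    merged = merged.join(alleles, on="snp_id")
    sign = np.sign(merged["beta"]).astype(float)
    risk = merged["risk_allele"]
    direction = pd.Series(pd.NA, index=merged.index, dtype="Float64")
    is_alt = risk.notna() & (risk == merged["alt_allele"])
    is_ref = risk.notna() & (risk == merged["ref_allele"])
    direction[is_alt] = sign[is_alt]
    direction[is_ref] = -sign[is_ref]
    unmatched = risk.notna() & ~is_alt & ~is_ref
    if unmatched.any():
        logger.warning("annotate_eqtls: %d record(s) with risk allele matching "
                       "neither ref nor alt; direction absent", int(unmatched.sum()))
    out = pd.DataFrame({
        "snp_id": merged["snp_id"],
        "annotation": merged["annotation"],
        "evidence_level": merged["evidence_level"],
        "mirna_id": merged["y_id"],
        "p": merged["p"],
        "beta_alt": merged["beta"],
        "direction_risk": direction,
    })
    return out.reset_index(drop=True)


def pharmacogenetic_screen(
    eqtls: pd.DataFrame,
    catalog: pd.DataFrame,
    nulls: NullSetCollection,
    snps: pd.DataFrame,
    p_max: float = 1e-3,
    levels: list[int] | None = None,
) -> tuple[EnrichmentResult, pd.DataFrame]:
    """Overlap enrichment of catalog (pharmacogenetic) SNPs with miRNA-associated SNPs.

    The query is the catalog's SNPs (optionally restricted to the given
    evidence ``levels``); the target is the set of SNPs with any miRNA
    association at p < ``p_max``. Returns the enrichment result and the
    annotated table of qualifying records.
    """
    cat = catalog
    if levels is not None:
        cat = cat[cat["evidence_level"].isin(levels)]
        if cat.empty:
            raise ValidationError(f"no catalog entries at evidence levels {levels}")
    query = list(dict.fromkeys(cat["snp_id"]))
    target = set(eqtls.loc[eqtls["p"] < p_max, "x_id"])
    result = overlap_enrichment(query, target, nulls)
    annotated = annotate_eqtls(eqtls, cat, snps, p_max=p_max)
    return result, annotated
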