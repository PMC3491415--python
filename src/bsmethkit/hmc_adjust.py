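"""Adjusting apparent 5mC levels for 5-hydroxymethylcytosine.

Conventional bisulfite sequencing cannot distinguish 5-methylcytosine from
5-hydroxymethylcytosine: both resist conversion and are read as C.  Paired
protocols (oxidative or TAB variants) measure the 5hmC fraction at the same
cytosines, which can then be subtracted from the apparent 5mC signal to
estimate true methylation.  The adjustment here is level subtraction floored
at zero, with counts re-derived from the 5mC sample's coverage.
"""

from __future__ import annotations

import logging

import numpy as np

from .datamodel_io import SampleMethylome, ValidationError, round_half_up

logger = logging.getLogger("bsmethkit")

_KEY = ["chrom", "start", "strand"]


def adjust_mc_for_hmc(mc: SampleMethylome, hmc: SampleMethylome) -> SampleMethylome:
    """Subtract 5hmC percent levels from apparent 5mC levels per base.

    On bases covered in both samples: adjusted% = max(0, mc% - hmc%);
    adjusted n_meth = round_half_up(coverage_mc * adjusted% / 100) and
    n_unmeth = coverage_mc - n_meth, so coverage is conserved.  Bases absent
    from the 5hmC sample pass through unchanged (their count is logged);
    bases covered only in 5hmC are ignored.  The operation is pure — applying
    it twice subtracts twice.
    """
    if mc.resolution != "base" or hmc.resolution != "base":
        raise ValidationError("adjust_mc_for_hmc expects base-resolution methylomes")
    if mc.context != hmc.context:
        raise ValidationError("5mC and 5hmC samples must share context")
    if len(mc) == 0:
        return mc.with_records(mc.df)

    hmc_pct = hmc.df[_KEY].copy()
    hmc_pct["hmc_percent"] = hmc.percent.to_numpy()
    merged = mc.df.merge(hmc_pct, on=_KEY, how="left")

    matched = merged["hmc_percent"].notna().to_numpy()
    n_pass = int((~matched).sum())
    if n_pass:
        logger.info("adjust_mc_for_hmc: %d bases lack 5hmC coverage; passed through", n_pass)

    cov = (merged["n_meth"] + merged["n_unmeth"]).to_numpy()
    mc_pct = 100.0 * merged["n_meth"].to_numpy() / cov
    adj_pct = np.where(matched, np.maximum(0.0, mc_pct - merged["hmc_percent"].fillna(0.0)), mc_pct)
    n_meth = np.where(matched, round_half_up(cov * adj_pct / 100.0), merged["n_meth"])

    out = merged[["chrom", "start", "end", "strand"]].copy()
    out["n_meth"] = n_meth.astype(np.int64)
    out["n_unmeth"] = cov - out["n_meth"]
    return mc.with_records(out)
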