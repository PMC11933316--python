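"""Tiling-screen analysis: per-sgRNA survival rates and domain-as-gene β.

In a tiling (domain-scanning) screen, guides are spread along one gene's
coding region.  Two complementary read-outs are computed:

* **Survival rate** per sgRNA and day: counts are depth-normalized
  (counts-per-million), replicate-averaged, a drug/vehicle ratio is formed
  per sgRNA (with a +0.5 pseudocount guarding zero counts in these tiny
  libraries), and ratios are rescaled so the mean over the non-targeting
  controls is exactly 1.  S < 1 marks a region whose disruption
  sensitizes cells to the drug.

* **Domain β-scores**: each domain is treated as a "gene" targeted by its
  tiling guides and fitted with the same negative-binomial MLE as the
  genome-wide screen.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ConfigError, ConsistencyError, NormalizationError
from .library import CountMatrix, SgRNALibrary
from . import beta as _beta

__all__ = ["survival_rates", "domain_beta"]


def survival_rates(cm: CountMatrix, library: SgRNALibrary,
                   ntc_ids=None, days=None, *,
                   treat: str = "DAC", control: str = "DMSO",
                   pseudocount: float = 0.5) -> pd.DataFrame:
    """Non-targeting-control-normalized drug/vehicle count ratios.

    Returns a long DataFrame ``sgRNA, gene, domain, cds_pos, day,
    survival_rate``.  Days without both arms are skipped with a warning.
    """
    ntc_ids = list(ntc_ids) if ntc_ids is not None else library.ntc_ids
    if not ntc_ids:
        raise ConfigError("non-targeting control set is empty; survival rates "
                          "require NTC normalization")
    missing = set(ntc_ids) - set(cm.counts.index)
    if missing:
        raise ConsistencyError(f"NTC sgRNA {sorted(missing)[0]!r} not in counts")

    norm = cm.cpm()
    meta = cm.samples
    if days is None:
        days = sorted(d for d in meta["day"].unique() if d > 0)

    ann = library.table.set_index("sgRNA")[["gene", "domain", "cds_pos"]]
    ann = ann.reindex(cm.counts.index)
    rows = []
    for day in days:
        sel_t = meta.index[(meta["condition"] == treat) & (meta["day"] == day)]
        sel_c = meta.index[(meta["condition"] == control) & (meta["day"] == day)]
        if len(sel_t) == 0 or len(sel_c) == 0:
            warnings.warn(f"day {day}: missing {treat} or {control} samples; skipped")
            continue
        avg_t = norm[list(sel_t)].mean(axis=1)
        avg_c = norm[list(sel_c)].mean(axis=1)
        rho = (avg_t + pseudocount) / (avg_c + pseudocount)
        ntc_mean = float(rho.loc[ntc_ids].mean())
        if ntc_mean == 0.0 or not np.isfinite(ntc_mean):
            raise NormalizationError(f"day {day}: NTC mean ratio is zero")
        S = rho / ntc_mean
        for sg, val in S.items():
            rows.append((sg, ann.loc[sg, "gene"], ann.loc[sg, "domain"],
                         ann.loc[sg, "cds_pos"], day, float(val)))
    if not rows:
        raise ConsistencyError("no day with paired samples; nothing computed")
    return pd.DataFrame(rows, columns=["sgRNA", "gene", "domain", "cds_pos",
                                       "day", "survival_rate"])


def domain_beta(cm: CountMatrix, library: SgRNALibrary,
                design: pd.DataFrame | None = None, *,
                per_replicate: bool = True, **fit_kwargs):
    """β-scores with each domain treated as a gene.

    Targeting guides are regrouped by their domain label (guides without a
    label are skipped with a warning); non-targeting and positive-control
    guides stay out of the domain groups.  Delegates to
    :func:`screenpulse.beta.fit_screen`, so normalization and the NB model
    are identical to the genome-wide analysis.
    """
    tab = library.table.copy()
    targeting = tab["class"] == "targeting"
    no_domain = targeting & tab["domain"].isna()
    if no_domain.any():
        warnings.warn(f"{int(no_domain.sum())} targeting sgRNA(s) without a "
                      f"domain label skipped")
        tab = tab[~no_domain]
        targeting = tab["class"] == "targeting"
    if not targeting.any():
        raise ConfigError("library has no domain-labelled targeting sgRNA")
    tab.loc[targeting, "gene"] = tab.loc[targeting, "domain"].astype(str)
    grouped = SgRNALibrary(tab.reset_index(drop=True))
    return _beta.fit_screen(cm, grouped, design, per_replicate=per_replicate,
                            **fit_kwargs)
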