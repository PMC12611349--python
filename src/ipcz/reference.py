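"""Published conservation-status reference for IPCZ mollusks.

The regional assessment this pipeline targets reports a per-class
cross-tabulation of mollusk species of conservation concern: IUCN Red List
category counts for Gastropoda / Bivalvia / Cephalopoda / Polyplacophora /
Scaphopoda, plus CITES Appendix II counts, with two Cephalopoda species
dual-listed (one DD + Appendix II, one NT + Appendix II). The species-level
list itself is not redistributable, so this module reconstructs a synthetic
species-level table with exactly those marginal counts; cross-tabulating it
must reproduce the published per-class totals (148 Gastropoda, 14 Bivalvia,
73 Cephalopoda, 1 Polyplacophora; 173 Least Concern overall; 12 species in
CITES Appendix II).
"""

from __future__ import annotations

import pandas as pd

# IUCN category -> per-class species counts, as published.
_IUCN_COUNTS = {
    "CR": {"Gastropoda": 3, "Bivalvia": 1},
    "VU": {"Gastropoda": 1},
    "EN": {"Gastropoda": 7, "Bivalvia": 1},
    "NT": {"Gastropoda": 2, "Cephalopoda": 1, "Polyplacophora": 1},
    "LC": {"Gastropoda": 126, "Bivalvia": 2, "Cephalopoda": 45},
    "DD": {"Gastropoda": 9, "Bivalvia": 2, "Cephalopoda": 25},
}

# CITES Appendix II per-class species counts, as published.
_CITES_COUNTS = {"Bivalvia": 8, "Cephalopoda": 4}

# Dual listings (counted in both tables above, once in class totals):
# one Cephalopoda DD + App II, one Cephalopoda NT + App II.
_DUAL = [("Cephalopoda", "DD"), ("Cephalopoda", "NT")]


def conservation_status_reference() -> pd.DataFrame:
    """Synthetic species-level status list matching the published cross-tab.

    Returns columns (species, taxon_class, iucn, cites_appendix). Species
    names are placeholders; only the marginal counts are meaningful.
    """
    rows: list[dict] = []
    counter = 0

    def add(taxon_class: str, iucn: str, cites: str) -> None:
        nonlocal counter
        rows.append(
            {
                "species": f"ref_sp_{counter:04d}",
                "taxon_class": taxon_class,
                "iucn": iucn,
                "cites_appendix": cites,
            }
        )
        counter += 1

    dual_budget = {k: dict.fromkeys([c for cc, c in _DUAL if cc == k], 1) for k in {c for c, _ in _DUAL}}
    for iucn, per_class in _IUCN_COUNTS.items():
        for taxon_class, n in per_class.items():
            n_dual = dual_budget.get(taxon_class, {}).get(iucn, 0)
            for i in range(n):
                add(taxon_class, iucn, "II" if i < n_dual else "none")

    # CITES-only species (Appendix II minus the dual-listed ones), IUCN = NE
    dual_per_class = {c: sum(1 for cc, _ in _DUAL if cc == c) for c, _ in _DUAL}
    for taxon_class, n in _CITES_COUNTS.items():
        for _ in range(n - dual_per_class.get(taxon_class, 0)):
            add(taxon_class, "NE", "II")

    return pd.DataFrame(rows)
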