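"""Generate the packaged default panel fixture (synthetic, not vendor data).

Writes ``src/metaboextract/data/default_panel.csv`` and ``default_istds.csv``:
a 188-metabolite roster with the canonical class counts (21 AA, 21 BA, 40 AC,
38 PCaa, 38 PCae, 14 lysoPC, 15 SM, 1 H1), plausible analyte names, elemental
formulas for the LC analytes, placeholder detection/quantification limits, and
an ISTD map with 13 shared FIA lipid/acylcarnitine ISTDs, one hexose ISTD, and
dedicated labeled ISTDs for the LC analytes (the taurine ISTD sits +2 Da above
the analyte; all other labels +3 Da).

Deterministic; run from the repository root:  python scripts/make_default_panel.py
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "src" / "metaboextract" / "data"

AA = {  # name -> formula
    "Alanine": "C3H7NO2", "Arginine": "C6H14N4O2", "Asparagine": "C4H8N2O3",
    "Aspartate": "C4H7NO4", "Citrulline": "C6H13N3O3", "Glutamine": "C5H10N2O3",
    "Glutamate": "C5H9NO4", "Glycine": "C2H5NO2", "Histidine": "C6H9N3O2",
    "Isoleucine": "C6H13NO2", "Leucine": "C6H13NO2", "Lysine": "C6H14N2O2",
    "Methionine": "C5H11NO2S", "Ornithine": "C5H12N2O2", "Phenylalanine": "C9H11NO2",
    "Proline": "C5H9NO2", "Serine": "C3H7NO3", "Threonine": "C4H9NO3",
    "Tryptophan": "C11H12N2O2", "Tyrosine": "C9H11NO3", "Valine": "C5H11NO2",
}

BA = {
    "Taurine": "C2H7NO3S", "Sarcosine": "C3H7NO2", "Acetyl-ornithine": "C7H14N2O3",
    "ADMA": "C8H18N4O2", "SDMA": "C8H18N4O2", "total DMA": "C8H18N4O2",
    "alpha-AAA": "C6H11NO4", "Carnosine": "C9H14N4O3", "Creatinine": "C4H7N3O",
    "Histamine": "C5H9N3", "Kynurenine": "C10H12N2O3",
    "Methionine sulfoxide": "C5H11NO3S", "Nitrotyrosine": "C9H10N2O5",
    "trans-4-Hydroxyproline": "C5H9NO3", "Phenylethylamine": "C8H11N",
    "Putrescine": "C4H12N2", "Serotonin": "C10H12N2O", "Spermidine": "C7H19N3",
    "Spermine": "C10H26N4", "DOPA": "C9H11NO4", "Dopamine": "C8H11NO2",
}

AC = [
    "C0", "C2", "C3", "C3:1", "C3-OH", "C4", "C4:1", "C4-OH", "C5", "C5:1",
    "C5:1-DC", "C5-DC", "C5-M-DC", "C5-OH", "C6", "C6:1", "C7-DC", "C8", "C9",
    "C10", "C10:1", "C10:2", "C12", "C12:1", "C12-DC", "C14", "C14:1",
    "C14:1-OH", "C14:2", "C14:2-OH", "C16", "C16:1", "C16:1-OH", "C16:2",
    "C16:2-OH", "C16-OH", "C18", "C18:1", "C18:1-OH", "C18:2",
]

PCAA = [
    "C24:0", "C26:0", "C28:1", "C30:0", "C30:2", "C32:0", "C32:1", "C32:2",
    "C32:3", "C34:1", "C34:2", "C34:3", "C34:4", "C36:0", "C36:1", "C36:2",
    "C36:3", "C36:4", "C36:5", "C36:6", "C38:0", "C38:1", "C38:3", "C38:4",
    "C38:5", "C38:6", "C40:1", "C40:2", "C40:3", "C40:4", "C40:5", "C40:6",
    "C42:0", "C42:1", "C42:2", "C42:4", "C42:5", "C42:6",
]

PCAE = [
    "C30:0", "C30:1", "C30:2", "C32:1", "C32:2", "C34:0", "C34:1", "C34:2",
    "C34:3", "C36:0", "C36:1", "C36:2", "C36:3", "C36:4", "C36:5", "C38:0",
    "C38:1", "C38:2", "C38:3", "C38:4", "C38:5", "C38:6", "C40:1", "C40:2",
    "C40:3", "C40:4", "C40:5", "C40:6", "C42:1", "C42:2", "C42:3", "C42:4",
    "C42:5", "C44:3", "C44:4", "C44:5", "C44:6", "C46:1",
]

LYSOPC = [
    "a C14:0", "a C16:0", "a C16:1", "a C17:0", "a C18:0", "a C18:1",
    "a C18:2", "a C20:3", "a C20:4", "a C24:0", "a C26:0", "a C26:1",
    "a C28:0", "a C28:1",
]

SM = [
    "C16:0", "C16:1", "C18:0", "C18:1", "C20:2", "C22:3", "C24:0", "C24:1",
    "C26:0", "C26:1", "(OH) C14:1", "(OH) C16:1", "(OH) C22:1", "(OH) C22:2",
    "(OH) C24:1",
]

HMDB = {
    "Taurine": "HMDB0000251", "Sarcosine": "HMDB0000271", "Lysine": "HMDB0000182",
    "Ornithine": "HMDB0000214", "Acetyl-ornithine": "HMDB0003357",
    "Glycine": "HMDB0000123", "Alanine": "HMDB0000161",
}

# placeholder per-class detection limits (µM in the measured extract), scaled
# so that typical tissue extracts censor acylcarnitines partially and lipids
# in aqueous buffer heavily, as in real class-yield profiles
LOD_BASE = {"AA": 1.0, "BA": 2.0, "AC": 2.0, "PCaa": 5.0, "PCae": 3.0,
            "lysoPC": 3.0, "SM": 2.0, "H1": 50.0}
ULOQ = {"AA": 1000.0, "BA": 500.0, "H1": 20000.0}


def slug(text: str) -> str:
    out = "".join(ch if ch.isalnum() else "_" for ch in text)
    while "__" in out:
        out = out.replace("__", "_")
    return out.strip("_")


def main() -> None:
    assert len(AA) == 21 and len(BA) == 21 and len(AC) == 40
    assert len(PCAA) == 38 and len(PCAE) == 38
    assert len(LYSOPC) == 14 and len(SM) == 15

    rng = np.random.default_rng(7)
    rows = []

    def add(name, cls, formula=None, istd=None):
        mode = "LC" if cls in ("AA", "BA") else "FIA"
        lod = round(LOD_BASE[cls] * float(rng.lognormal(0.0, 0.3)), 4)
        uloq = ULOQ.get(cls)
        if name == "Taurine":
            uloq = 1000.0
        lloq = round(lod * 3.0, 4) if uloq is not None else None
        rows.append(
            dict(
                id=slug(f"{cls}_{name}") if cls not in ("AA", "BA", "H1") else slug(name),
                name=name,
                hmdb_id=HMDB.get(name, ""),
                compound_class=cls,
                ms_mode=mode,
                lod_uM=lod,
                lloq_uM=lloq,
                uloq_uM=uloq,
                istd_id=istd,
                formula=formula or "",
                quant_type="quantitative" if mode == "LC" else "semi_quantitative",
            )
        )

    istd_rows = []

    for name, formula in AA.items():
        istd = f"ISTD_{slug(name)}"
        istd_rows.append(dict(istd_id=istd, name=f"{name} ISTD", ms_mode="LC",
                              formula="", mass_shift_Da=3))
        add(name, "AA", formula, istd)
    for name, formula in BA.items():
        istd = f"ISTD_{slug(name)}"
        shift = 2 if name == "Taurine" else 3
        istd_rows.append(dict(istd_id=istd, name=f"{name} ISTD", ms_mode="LC",
                              formula="", mass_shift_Da=shift))
        add(name, "BA", formula, istd)

    # 13 shared FIA lipid/acylcarnitine ISTDs + one hexose ISTD
    fia_istds = {
        "ISTD_AC_short": "d3-C2 carnitine", "ISTD_AC_medium": "d3-C8 carnitine",
        "ISTD_AC_long": "d3-C16 carnitine", "ISTD_AC_free": "d9-C0 carnitine",
        "ISTD_lysoPC": "lysoPC a C18:0 (d4)",
        "ISTD_PCaa_low": "PC aa C28:0 (d6)", "ISTD_PCaa_mid": "PC aa C36:0 (d6)",
        "ISTD_PCaa_high": "PC aa C42:0 (d6)",
        "ISTD_PCae_low": "PC ae C30:0 (d6)", "ISTD_PCae_mid": "PC ae C38:0 (d6)",
        "ISTD_PCae_high": "PC ae C44:0 (d6)",
        "ISTD_SM_low": "SM C16:0 (d3)", "ISTD_SM_high": "SM C24:0 (d3)",
    }
    for iid, nm in fia_istds.items():
        istd_rows.append(dict(istd_id=iid, name=nm, ms_mode="FIA", formula="",
                              mass_shift_Da=""))
    istd_rows.append(dict(istd_id="ISTD_H1", name="13C6-glucose", ms_mode="FIA",
                          formula="", mass_shift_Da=""))

    ac_groups = ["ISTD_AC_free"] + ["ISTD_AC_short"] * 16 + ["ISTD_AC_medium"] * 8 \
        + ["ISTD_AC_long"] * 15
    for name, istd in zip(AC, ac_groups):
        add(name, "AC", None, istd)
    for i, name in enumerate(PCAA):
        istd = ["ISTD_PCaa_low", "ISTD_PCaa_mid", "ISTD_PCaa_high"][min(i // 13, 2)]
        add(f"PC aa {name}", "PCaa", None, istd)
    for i, name in enumerate(PCAE):
        istd = ["ISTD_PCae_low", "ISTD_PCae_mid", "ISTD_PCae_high"][min(i // 13, 2)]
        add(f"PC ae {name}", "PCae", None, istd)
    for name in LYSOPC:
        add(f"lysoPC {name}", "lysoPC", None, "ISTD_lysoPC")
    for i, name in enumerate(SM):
        add(f"SM {name}", "SM", None, "ISTD_SM_low" if i < 8 else "ISTD_SM_high")
    add("Hexoses", "H1", "C6H12O6", "ISTD_H1")

    panel = pd.DataFrame(rows)
    assert len(panel) == 188, len(panel)
    assert panel["id"].is_unique
    istds = pd.DataFrame(istd_rows)
    assert istds["istd_id"].is_unique
    fia_lipid = istds[istds["istd_id"].isin(fia_istds)]
    assert len(fia_lipid) == 13

    OUT.mkdir(parents=True, exist_ok=True)
    panel.to_csv(OUT / "default_panel.csv", index=False)
    istds.to_csv(OUT / "default_istds.csv", index=False)
    print(f"wrote {OUT / 'default_panel.csv'} ({len(panel)} metabolites)")
    print(f"wrote {OUT / 'default_istds.csv'} ({len(istds)} ISTDs)")


if __name__ == "__main__":
    main()
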