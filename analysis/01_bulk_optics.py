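"""Bulk optical parameters: derived quantities and group comparisons.

Loads the measured normal/malignant ovarian-stroma optics at the laser
(890 nm) and SHG (457 nm) wavelengths, recomputes the reduced scattering
coefficient and mean free path, forms the spectral-slope fold-increases,
and runs pooled two-sided t-tests between the tissue classes.

Writes results/bulk_optics.csv and results/table2_pvalues.csv.
"""

from pathlib import Path

import pandas as pd

from shgquant.optics import (
    group_summary,
    load_bulk_optics,
    mean_free_path,
    reduced_scattering,
    spectral_slope_ratio,
)
from shgquant.stats import pooled_ttest_from_summary

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

table = load_bulk_optics()
table["mu_s_prime_recomputed"] = [
    reduced_scattering(r.mu_s, r.g) for r in table.itertuples()
]
table["mfp_um"] = [mean_free_path(r.mu_s) for r in table.itertuples()]
table.to_csv(OUT / "bulk_optics.csv", index=False)

print("Measured bulk optics with derived quantities:")
print(table.to_string(index=False))

print("\nSpectral slope of mu_s' (fold increase, 890 nm -> 457 nm):")
for tissue in ("normal", "cancer"):
    fold = spectral_slope_ratio(
        group_summary(tissue, 457, "mu_s_prime").mean,
        group_summary(tissue, 890, "mu_s_prime").mean,
    )
    print(f"  {tissue}: {fold:.2f}x")
print("The steeper normal-tissue slope (~3x vs ~1.6x) points to mass-fractal")
print("refractive-index organization in normal stroma versus similar-size")
print("scatterers in the malignant tissue.")

rows = []
for quantity in ("mu_s", "mu_a", "g", "mu_s_prime"):
    for wl in (890, 457):
        t, df, p = pooled_ttest_from_summary(
            group_summary("cancer", wl, quantity), group_summary("normal", wl, quantity)
        )
        rows.append((quantity, wl, round(t, 4), df, round(p, 6)))
pvals = pd.DataFrame(rows, columns=["quantity", "wavelength_nm", "t", "df", "p"])
pvals.to_csv(OUT / "table2_pvalues.csv", index=False)
print("\nCancer-vs-normal pooled t-tests (from group summaries):")
print(pvals.to_string(index=False))
print("\nScattering at the SHG wavelength separates the classes (p ~ 0.008),")
print("as does mu_s' at both wavelengths; absorption never does.")
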