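"""Raw reducing-sugar assay readings → digestion-extent values.

The colorimetric (PAHBAH) assay reads absorbance against a single-point
maltose standard. The conversion chain is unit-coherent throughout:

    concentration in the read aliquot   (dA_sample / dA_standard) × c_std  [mmol/L]
    → maltose in the aliquot            × aliquot volume                   [mmol]
    → maltose mass                      × 342 mg/mmol                      [mg]
    → maltose in the whole vessel       × dilution factor                  [mg]
    → starch-equivalent mass            × 324/342          (starch basis only)
    → fraction of substrate mass        ÷ starch (or carbohydrate) mass, ×100

Glycemic load is the classical product GI × available-carbohydrate fraction.
"""

from __future__ import annotations

from .types import AbsorbanceRecord, ConversionConstants, SampleMeta

__all__ = [
    "maltose_mass_in_vessel_mg",
    "absorbance_to_percent_digested",
    "absorbance_to_normalized_reducing_sugar",
    "glycemic_load",
]


def maltose_mass_in_vessel_mg(rec: AbsorbanceRecord, consts: ConversionConstants) -> float:
    """Maltose-equivalent mass (mg) released into the digestion vessel."""
    conc_mmol_per_L = rec.dA_sample / rec.dA_standard * rec.standard_conc_mmol_per_L
    aliquot_L = rec.aliquot_volume_uL * 1e-6
    return conc_mmol_per_L * aliquot_L * consts.maltose_mw * consts.dilution_factor


def absorbance_to_percent_digested(
    rec: AbsorbanceRecord, meta: SampleMeta, consts: ConversionConstants
) -> float:
    """Percent of the sample's starch digested at ``rec.time_min``.

    The maltose mass in the vessel is converted to its starch-equivalent
    mass (×324/342, maltose → two anhydroglucose units) and expressed as a
    percentage of the starch substrate loaded.
    """
    starch_mg = meta.starch_mass_mg
    if starch_mg <= 0:
        raise ValueError(
            f"{meta.sample_id}: zero starch mass — use the "
            "REDUCING_SUGAR_NORMALIZED basis for starch-free samples"
        )
    maltose_mg = maltose_mass_in_vessel_mg(rec, consts)
    return maltose_mg * consts.starch_to_maltose_weight_ratio / starch_mg * 100.0


def absorbance_to_normalized_reducing_sugar(
    rec: AbsorbanceRecord, meta: SampleMeta, consts: ConversionConstants
) -> float:
    """Released reducing sugar normalized to total carbohydrates (×100).

    Same chain as :func:`absorbance_to_percent_digested` but without the
    maltose→starch weight conversion, normalized by total carbohydrate mass.
    """
    carb_mg = meta.carb_mass_mg
    if carb_mg <= 0:
        raise ValueError(f"{meta.sample_id}: zero total-carbohydrate mass")
    return maltose_mass_in_vessel_mg(rec, consts) / carb_mg * 100.0


def glycemic_load(gi: float, carb_pct: float) -> float:
    """Glycemic load GL = GI × available carbohydrate fraction, to 2 dp."""
    if gi < 0:
        raise ValueError("gi must be >= 0")
    if not (0.0 <= carb_pct <= 100.0):
        raise ValueError("carb_pct must lie in [0, 100]")
    return round(gi * carb_pct / 100.0, 2)
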