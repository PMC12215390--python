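"""Chemistry presets and benchmark reference tables.

The conversion-probability presets are named after the chemical conversion
protocols commonly combined with 4sU metabolic labeling (IAA = iodoacetamide,
mCPBA = meta-chloroperoxy-benzoic acid, TFEA = 2,2,2-trifluoroethylamine,
NaIO4 = sodium periodate), applied either in situ (inside intact fixed cells)
or on beads (after mRNA capture on barcoded beads).

The preset values are the observed mean T-to-C substitution rates of each
method, used here as default induced conversion probabilities (``p_c``) for
the simulator. They are approximations: an observed raw rate conflates the
true per-uridine conversion probability of new molecules, the fraction of new
molecules in the pool, and the background rate, so treat these as
order-of-magnitude realistic defaults, not chemistry constants.
"""

from __future__ import annotations

#: Default induced T-to-C conversion probability per chemistry/platform preset.
#: ``"control"`` means no chemistry: p_c falls back to the background rate.
CHEMISTRY_PRESETS: dict[str, float | None] = {
    "control": None,
    "mcpba_tfea_ph7.4": 0.0840,
    "mcpba_tfea_ph5.2": 0.0811,
    "naio4_tfea_ph5.2": 0.0819,
    "onbeads_iaa_32c": 0.0639,
    "onbeads_iaa_37c": 0.0384,
    "c4_onbeads_iaa_32c": 0.0844,
    "c4_insitu_iaa_ph8": 0.0574,
    "dropseq_insitu_iaa_ph8": 0.0353,
    "insitu_iaa_ph8": 0.0262,
}

#: Observed benchmark metrics per method (percent scale where applicable).
#: ``mean_tc_rate_pct`` is the group-mean T-to-C substitution rate;
#: ``labeled_umi_pct`` the mean fraction of UMIs carrying >=1 T-to-C call.
#: These are measured reference numbers shipped as inputs for worked examples
#: (e.g. fold-difference between matched chemistries), not computed here.
METHOD_BENCHMARKS: dict[str, dict[str, float]] = {
    "mcpba_tfea_ph7.4": {"mean_tc_rate_pct": 8.40},
    "mcpba_tfea_ph5.2": {"mean_tc_rate_pct": 8.11},
    "naio4_tfea_ph5.2": {"mean_tc_rate_pct": 8.19},
    "onbeads_iaa_32c": {"mean_tc_rate_pct": 6.39, "labeled_umi_pct": 36.87},
    "onbeads_iaa_37c": {"mean_tc_rate_pct": 3.84, "labeled_umi_pct": 45.98},
    "c4_onbeads_iaa_32c": {"mean_tc_rate_pct": 8.44},
    "c4_insitu_iaa_ph8": {"mean_tc_rate_pct": 5.74},
    "dropseq_insitu_iaa_ph8": {"mean_tc_rate_pct": 3.53},
    # Matched-pair group means for the same chemistry run on beads vs in situ.
    "onbeads_iaa_matched": {"mean_tc_rate_pct": 6.07},
    "insitu_iaa_matched": {"mean_tc_rate_pct": 2.62},
}


def preset_conversion_probability(name: str, background_pe: float) -> float:
    """Resolve a chemistry preset to an induced conversion probability.

    The control preset (no chemical conversion) resolves to the background
    rate so that "new" molecules are indistinguishable from old ones.
    """
    try:
        value = CHEMISTRY_PRESETS[name]
    except KeyError:
        raise KeyError(
            f"unknown chemistry preset {name!r}; known presets: "
            f"{sorted(CHEMISTRY_PRESETS)}"
        ) from None
    return background_pe if value is None else value
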