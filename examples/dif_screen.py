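"""Screening for differential item functioning between gender groups.

Injects uniform DIF (a 0.5 threshold shift for men) into one item of a
synthetic cohort and runs the ordinal-logistic-regression screen: three
nested proportional-odds models per item, likelihood-ratio tests, the
beta-change operating rule (>1%) and the McFadden pseudo-R^2 severity
measure.  Then rescores with group-specific parameters for the flagged
item and checks how much the scores actually move.
"""

import cesdcat as cc

bank = cc.cesd_item_bank()
design = cc.SimulationDesign(
    bank=bank, n_persons=1500, dif_items=[("q9", "male", 0.5, 1.0)], seed=11
)
data = cc.make_study_dataset(design)

res = cc.detect_dif(data, "group", bank=bank)
cols = ["item_id", "lr_chi2_total", "p_total", "beta_change",
        "pseudo_r2_change", "flagged"]
print(res.table[cols].to_string(index=False, float_format="%.4f"))
print(f"\nflagged items: {res.flagged_items}")

orig, adj, r, t = cc.dif_adjusted_scores(data, "group", res.flagged_items,
                                         bank=bank)
print(f"original vs DIF-adjusted person scores: r = {r:.4f}, t = {t:.3f}")
print("Reading: a high correlation means the detected DIF is practically "
      "ignorable; group-specific parameters would barely move anyone's score.")
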