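"""Score donor-site damage: published score deltas and a PWM example.

The CLCNKB exon 2 boundary variants weaken the 5' donor site.  Their
published maximum-entropy scores are packaged as inputs; the percent change
100*(mut - wt)/wt summarises the loss.  A PWM scorer handles the same
arithmetic for user-supplied or synthetic models.
"""

from exonskip import delta_from_scores, site_delta
from exonskip.fixtures import load_maxent_scores
from exonskip.synthetic import make_donor_pwm

print("published donor-score drops (CLCNKB exon 2 boundary):")
for _, row in load_maxent_scores().iterrows():
    d = delta_from_scores(row["wt_score"], row["mut_score"])
    print(f"  {row['hgvs_c']:10s} {row['wt_score']:.2f} -> {row['mut_score']:.2f}  "
          f"delta {d.delta:+.2f}  ({d.percent_change_2dp():+.2f}%)  "
          f"loss flagged: {d.flagged_loss}")

# A PWM trained on GT-containing donor windows: destroying the invariant GT
# of a strong site is always flagged as a loss.
model = make_donor_pwm(seed=0)
wt = "CAGGTAAGT"          # 3 exonic nt | GT + 4 intronic nt
mut = wt[:3] + "AT" + wt[5:]  # G of the invariant GT mutated
d = site_delta(model, wt, mut)
print(f"\nsynthetic donor {wt} -> {mut}:")
print(f"  PWM log-odds {d.wt_score:.2f} -> {d.mut_score:.2f} "
      f"(delta {d.delta:+.2f}, loss flagged: {d.flagged_loss})")
# Negative delta = the mutant junction looks less like a donor site to the
# model; percent change is the reporting convention for such losses.
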