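"""Score a response pattern on the Swedish anxiety bank.

Loads the bundled 15-item anxiety calibration, scores one response vector
with EAP, and converts the estimate to the PROMIS T-score metric.
"""

import promis_irt as pi

bank = pi.load_item_bank("anxiety_sv")

# moderate endorsement: mostly "sometimes" with a few higher categories
responses = [2, 2, 1, 2, 3, 1, 2, 2, 1, 0, 1, 2, 1, 2, 2]
est = pi.eap_score(responses, bank)

print(f"items answered : {est.n_items_used}")
print(f"theta (EAP)    : {est.theta:.3f}  (SE {est.se:.3f})")
print(f"T-score        : {est.tscore:.1f}")
print(f"reliability    : {est.reliability:.3f}")
# theta is symptom severity on a standard-normal reference scale;
# T = 10*theta + 50, and reliability = 1 - SE^2 at this trait level.
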