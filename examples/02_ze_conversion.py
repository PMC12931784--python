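"""From a linguistic expert judgment to a consensus-weighted fuzzy rating.

One decision-maker rates a failure mode's severity "Very Low" and declares
their own reliability "Very Low"; a 12-member panel votes 7 agree / 2
disagree / 3 neutral on that assessment.  The ZE conversion turns this into
a single TFN: the rating shrunk towards zero by the square root of the
consensus-adjusted reliability.
"""

from zefmea import (
    VoteRecord,
    ZEJudgment,
    ZJudgment,
    adjust_reliability,
    consensus_ratio,
    crisp_reliability,
    rating_scale,
    reliability_scale,
    ze_convert,
)

rating = rating_scale()
reliability = reliability_scale()

judgment = ZJudgment(rating_term="VL", reliability_term="VL")
vote = VoteRecord(agree=7, disagree=2, neutral=3, panel_size=12)

b = crisp_reliability(reliability.lookup(judgment.reliability_term))
R = consensus_ratio(vote)
b_star = adjust_reliability(b, R)
print(f"intrinsic reliability b  = {b:.3f}")     # GMIR of (0, 0, 0.3) -> 0.05
print(f"consensus ratio R        = {R:.3f}")     # (7-2)/(12-3) = 0.556
print(f"adjusted reliability b*  = {b_star:.3f}")  # agreement pulls b towards 1

converted = ze_convert(ZEJudgment(judgment, vote), rating, reliability)
print(f"ZE-converted severity    = {converted}")
# sqrt(b*) * (0, 1, 2): a weak rating, partially rehabilitated by the panel
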