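"""Compare two domain choppings with intersection-over-union.

Scores a 2-domain prediction against a 3-domain reference annotation, the
kind of disagreement different domain databases routinely show for the
same protein. Domains are matched one-to-one by optimal assignment; the
mean divides by the larger domain count, so over- and under-splitting are
penalized symmetrically.
"""

from paedomains import match_and_score, parse_chopping_string

predicted = parse_chopping_string("1-150,151-300")
reference = parse_chopping_string("1-100,101-200,201-300")

report = match_and_score(predicted, reference)
for p, r, iou in report.per_pair:
    print(f"predicted domain {p + 1} <-> reference domain {r + 1}: IoU {iou:.3f}")
print(f"mean IoU: {report.mean_iou:.3f}  (n_pred={report.n_pred}, n_ref={report.n_ref})")
# The unmatched reference domain counts as zero, so the mean reflects both
# boundary accuracy and agreement on the number of domains.
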