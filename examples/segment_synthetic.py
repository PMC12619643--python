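"""Segment a synthetic three-domain protein and score it against the truth.

Generates a 300-residue PAE matrix with three planted domains (80, 120 and
100 residues), runs the default pipeline (contrast threshold T=2 Å, Leiden
resolution 0.7, minimum domain size 10) and prints the resulting chopping
next to the planted ground truth.
"""

from paedomains import PlantedSpec, generate, match_and_score, segment_pae, to_chopping_string

pae, truth = generate(PlantedSpec(domain_lengths=(80, 120, 100), seed=0))
result = segment_pae(pae)
seg = result.segmentation

print(f"residues:        {pae.n}")
print(f"clusters found:  {result.assignment.k}")
print(f"predicted:       {to_chopping_string(seg)}")
print(f"ground truth:    {to_chopping_string(truth)}")
print(f"mean IoU:        {match_and_score(seg, truth).mean_iou:.3f}")
# The chopping lists each domain as start-end residue ranges; a mean
# intersection-over-union of 1.0 means every domain boundary was recovered
# exactly.
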