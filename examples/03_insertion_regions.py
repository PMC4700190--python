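"""Detect the spiral-former insertion regions in an alignment.

Uses the packaged synthetic alignment: a CynD-like sequence with both
C-surface insertions, a beta-alanine-synthase-like homolog whose region 1
is eight residues shorter, and a non-spiral reference with neither.  The
detector should report exactly 55-72 (18 residues) and 222-235 (14) for
the CynD-like member.
"""

from spiralscan import detect_insertion_regions, map_region_between_sequences
from spiralscan.synthetic import cynd_like_alignment

aln, truth = cynd_like_alignment(seed=0)
regions = detect_insertion_regions(aln, reference_id="nonspiral_ref", query_id="CynD_Bpum")

for i, r in enumerate(regions, start=1):
    print(f"region {i}: residues {r.start}-{r.end} ({r.length} residues, "
          f"alignment columns {r.column_start}-{r.column_end})")

mapped = map_region_between_sequences(aln, regions[0], "bAS_Dmel")
print(f"region 1 on bAS_Dmel: {mapped.region.start}-{mapped.region.end}, "
      f"{mapped.length_difference} residues shorter than in CynD")
absent = map_region_between_sequences(aln, regions[0], "nonspiral_ref")
print(f"region 1 on the non-spiral reference: "
      f"{'absent (all gaps)' if absent.absent else 'present'}")
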