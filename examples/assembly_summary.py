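"""Assembly and annotation summary arithmetic on published table inputs.

Recomputes the headline assembly numbers of the P. tenella genome report
from its printed tables: the scaffold N50 implied by the eight chromosome
lengths, the chromosome anchoring ratio, BUSCO completeness, and the
repeat/annotation percentages.
"""

from popsweep import (
    LengthSet,
    anchoring_ratio,
    busco_summary,
    composition_percentages,
    nxx,
)

chroms = LengthSet(
    [f"Chr{i}" for i in range(1, 9)],
    [44_825_466, 29_024_987, 26_387_986, 25_637_364,
     23_141_640, 21_538_263, 19_226_261, 17_664_456],
)
scaffold_total = 231_208_648
contig_total = 231_191_648

print(f"scaffold N50 from chromosome lengths: "
      f"{nxx(chroms, 50, total_override=scaffold_total):,} bp")
print(f"chromosome anchoring ratio: "
      f"{anchoring_ratio(chroms, scaffold_total)}% of the assembly")
print(f"BUSCO completeness: "
      f"{busco_summary({'S': 1967, 'D': 42, 'C': 2009, 'total': 2121})}%")
comp = composition_percentages(
    {"TE_total": 66_966_690,
     "LTR": {"Copia": 8_454_829, "Gypsy": 18_247_107, "unknown": 15_756_928}},
    contig_total,
)
print(f"transposable elements: {comp['TE_total']}% of the genome "
      f"(LTR retrotransposons {comp['LTR']}%)")
print(f"Nr-annotated genes: "
      f"{composition_percentages({'Nr': 31_202}, 32_088)['Nr']}% of 32,088")
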