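"""Worked-example inputs: published summary numbers from a decidualization
methylome study of human endometrial stromal cells.

The study compared Infinium 450K beta-values between non-decidualized and
decidualized stromal cells from the same individuals.  Reproduced here as
plain inputs are (i) the headline counts of the differential-CpG tally and
(ii) the eleven differentially methylated CpG-gene pairs with their
condition-mean beta-values and expression fold changes, which together
exercise the delta-beta classifier and the fold-change rule on real
printed values.
"""

from __future__ import annotations

import pandas as pd

#: CpGs retained after detection-p and Y-chromosome filtering.
N_VALID_CPGS = 482_005

#: CpGs interrogated by the array before filtering.
N_ARRAY_CPGS = 482_421

#: Differential CpG counts reported at the two conventional |delta| cutoffs.
REPORTED_DIFFERENTIAL = {
    0.15: {"total": 582, "hypo": 210, "hyper": 372},
    0.30: {"total": 23, "hypo": 8, "hyper": 15},
}

#: Eleven genes with a differentially methylated CpG (|delta beta| > 0.30),
#: with condition-mean beta-values (non-decidualized, decidualized) and the
#: decidualized/non-decidualized expression ratio.  Ratios printed as 1
#: belong to genes without an expression change call.
DIFFERENTIAL_GENE_TABLE = pd.DataFrame(
    [
        ("NM_001032280", "TFAP2A", 0.001116211, 0.7699487, 0.602183089),
        ("NM_001099284", "ZNF239", 0.3894365, 0.7715948, 0.983577659),
        ("NM_006897", "HOXC9", 0.0, 0.3599297, 0.957752628),
        ("NR_001317", "HCG4P6", 0.0165225, 0.3242724, 0.935774769),
        ("NM_016078", "FAM18B", 0.004547609, 0.3047889, 1.023612243),
        ("NM_176810", "NLRP13", 0.5744109, 0.2743416, 1.0),
        ("NM_033554", "HLA-DPA1", 0.6535866, 0.3476084, 0.915018217),
        ("NM_006557", "DMRT2", 0.8715751, 0.5523196, 1.0),
        ("NM_181733", "COG5", 0.7118202, 0.3734171, 1.801646442),
        ("NM_000257", "MYH7", 0.7474061, 0.3890077, 1.0),
        ("NM_181838", "UBE2D2", 0.7447599, 0.374194, 1.885683062),
    ],
    columns=["refseq_id", "gene_symbol", "beta_nondecidualized",
             "beta_decidualized", "expression_ratio"],
)

#: Genes the study called differentially expressed among the eleven.
EXPRESSION_CHANGED_GENES = frozenset({"TFAP2A", "UBE2D2", "COG5"})
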