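"""Published reference values for grapevine veraison meta-QTLs.

Four veraison meta-QTLs on linkage groups 1 and 2 of the grapevine
consensus map are widely used as reference loci; their consensus-map
coordinates are reproduced here as input data for interval arithmetic
(CI spans, physical intervals) and for regression checks of the summary
code.  Coordinates are cM on the consensus map; physical positions are bp
on the 12X.v2 grapevine assembly.
"""

from __future__ import annotations

from .models import MetaQTL

#: name -> (lg, peak_cm, mean_r2, ci_start_cm, ci_end_cm, start_bp, end_bp)
VERAISON_METAQTL_TABLE = {
    "ver_1.1": ("1", 31.29, 0.11, 29.15, 33.43, 2_510_506, 3_254_952),
    "ver_2.1": ("2", 31.34, 0.17, 28.79, 33.89, 4_029_921, 5_344_816),
    "ver_2.2": ("2", 41.55, 0.13, 40.00, 43.30, 5_717_649, 7_154_894),
    "ver_2.3": ("2", 53.47, 0.34, 52.88, 54.07, 13_336_750, 16_677_137),
}


def veraison_metaqtls() -> list[MetaQTL]:
    """The reference veraison meta-QTLs as MetaQTL records."""
    out = []
    for name, (lg, peak, r2, lo, hi, bp_lo, bp_hi) in \
            VERAISON_METAQTL_TABLE.items():
        out.append(
            MetaQTL(name=name, lg=lg, peak_cm=peak, ci_start_cm=lo,
                    ci_end_cm=hi, mean_r2=r2, member_ids=[], n_studies=0,
                    traits=["ver"], chrom=f"chr{lg}", start_bp=bp_lo,
                    end_bp=bp_hi)
        )
    return out
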