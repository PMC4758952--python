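"""qPCR calculators: ChIP fold enrichment and ddCt relative expression."""

from __future__ import annotations

import math

__all__ = ["chip_fold_enrichment", "relative_expression"]


def _check_finite(*cts: float) -> None:
    for ct in cts:
        if not math.isfinite(ct):
            raise ValueError("Ct values must be finite")


def chip_fold_enrichment(input_ct: float, ip_ct: float) -> float:
    """ChIP fold enrichment over input: 2^(input Ct - IP Ct)."""
    _check_finite(input_ct, ip_ct)
    return 2.0 ** (input_ct - ip_ct)


def relative_expression(
    target_ct_treated: float,
    ref_ct_treated: float,
    target_ct_control: float,
    ref_ct_control: float,
) -> float:
    """Fold change of a target vs control, normalized to a reference gene.

    Standard ddCt with amplification efficiency fixed at 2:
    2^-((target_t - ref_t) - (target_c - ref_c)).
    """
    _check_finite(target_ct_treated, ref_ct_treated, target_ct_control, ref_ct_control)
    ddct = (target_ct_treated - ref_ct_treated) - (target_ct_control - ref_ct_control)
    return 2.0 ** (-ddct)
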