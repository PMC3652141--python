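"""Brain/blood partitioning predicted from PSA and Log P.

The model is the two-descriptor linear QSAR

    Log BB = -0.0148 * PSA + 0.152 * Log P + 0.139

where BB = C_brain / C_blood is the brain-to-blood concentration ratio and
Log BB its base-10 logarithm. Lipophilicity (Log P) raises predicted brain
exposure; polar surface area lowers it.

Reporting convention: predictions are kept at full precision internally.
The published 18-agent reference table rounds Log BB to three decimals and
derives BB from that *rounded* Log BB (verifiable from its most lipophilic
agent, where 10^(Log BB) before and after rounding differ in the third
decimal). :func:`display_row` reproduces that convention exactly.
"""

from __future__ import annotations

import dataclasses
import math
from decimal import ROUND_HALF_UP, Decimal
from typing import Sequence

from .chem_io import DescriptorTable
from .errors import InputError

#: Coefficients of the Log BB model: (PSA slope Å⁻², Log P slope, intercept).
PSA_COEF = -0.0148
LOGP_COEF = 0.152
INTERCEPT = 0.139


def round_half_away(x: float, ndigits: int = 3) -> float:
    """Round half away from zero (the convention of the reference tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(abs(x))).quantize(q, rounding=ROUND_HALF_UP)) * (
        1 if x >= 0 else -1
    )


def log_bb(psa: float, log_p: float) -> float:
    """Predicted base-10 log of the brain/blood concentration ratio."""
    if not (math.isfinite(psa) and math.isfinite(log_p)):
        raise InputError("psa and log_p must be finite")
    if psa < 0:
        raise InputError(f"psa must be non-negative, got {psa}")
    return PSA_COEF * psa + LOGP_COEF * log_p + INTERCEPT


def bb_ratio(log_bb_value: float) -> float:
    """BB = 10^LogBB, the brain-to-blood concentration ratio."""
    if not math.isfinite(log_bb_value):
        raise InputError("log_bb must be finite")
    return 10.0 ** log_bb_value


@dataclasses.dataclass(frozen=True)
class BBBPrediction:
    """Full-precision Log BB and BB for one compound."""

    agent_id: str
    log_bb: float
    bb: float

    def __post_init__(self) -> None:
        assert self.bb > 0
        assert abs(self.bb - 10.0 ** self.log_bb) <= 1e-12 * self.bb


def display_row(p: BBBPrediction) -> tuple[str, float, float]:
    """(agent_id, Log BB, BB) in the published 3-decimal convention.

    Log BB is rounded half-away-from-zero to 3 decimals; BB is 10 raised to
    the rounded Log BB, itself rounded to 3 decimals.
    """
    rlb = round_half_away(p.log_bb, 3)
    return (p.agent_id, rlb, round_half_away(10.0 ** rlb, 3))


def bbb_table(table: DescriptorTable) -> list[BBBPrediction]:
    """One prediction per record, order preserved."""
    preds = []
    for r in table:
        r.require(["psa", "log_p"])
        lb = log_bb(r.psa, r.log_p)
        preds.append(BBBPrediction(agent_id=r.agent_id, log_bb=lb, bb=bb_ratio(lb)))
    return preds


def bbb_summary(preds: Sequence[BBBPrediction], rounded: bool = False) -> dict:
    """Mean/SD/min/max of BB and mean Log BB over a set of predictions.

    SD is the sample standard deviation (n-1 denominator); at least two
    predictions are required. With ``rounded=True`` the statistics are taken
    over the 3-decimal display values instead of full precision (the two
    paths agree on mean and SD for the 18-agent reference set; min and max
    can differ in the last decimal).
    """
    if not preds:
        raise InputError("bbb_summary requires at least one prediction")
    if len(preds) < 2:
        raise InputError("sample SD undefined for a single prediction")
    if rounded:
        bbs = [display_row(p)[2] for p in preds]
        lbs = [display_row(p)[1] for p in preds]
    else:
        bbs = [p.bb for p in preds]
        lbs = [p.log_bb for p in preds]
    n = len(bbs)
    mean = sum(bbs) / n
    sd = math.sqrt(sum((x - mean) ** 2 for x in bbs) / (n - 1))
    return {
        "mean_bb": round_half_away(mean, 3),
        "sd_bb": round_half_away(sd, 3),
        "min_bb": round_half_away(min(bbs), 3),
        "max_bb": round_half_away(max(bbs), 3),
        "mean_log_bb": round_half_away(sum(lbs) / n, 3),
    }
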