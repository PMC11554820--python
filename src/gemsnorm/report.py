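"""Human- and machine-readable normative comparison reports.

Every number in a report is the output of a library operation (scoring,
single-case test, cut-off, change classification); the provenance block
records the hashes of the model and configuration that produced them so a
clinical output can be audited.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

from . import __version__
from .change import ChangeModel, classify_change
from .exceptions import ValidationError
from .normative import (
    ExamineeRecord,
    NormativeModel,
    cutoff_score,
    single_case_test,
)
from .scoring import ScoreProfile, round_half_up

__all__ = ["ComparisonReport", "build_report"]


def _hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, separators=(",", ":"))
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class ComparisonReport:
    examinee: dict
    profile: dict
    comparisons: list
    change: dict | None
    provenance: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {
                "examinee": self.examinee,
                "profile": self.profile,
                "comparisons": self.comparisons,
                "change": self.change,
                "provenance": self.provenance,
            },
            sort_keys=True,
            indent=1,
        )

    def to_text(self) -> str:
        lines = ["Normative comparison report", "=" * 27]
        ex = self.examinee
        lines.append(
            f"Examinee: age {ex['age']}, education {ex['education']} y, "
            f"sex {ex['sex']}, CR {ex['cr']}"
        )
        lines.append(f"Global score: {self.profile['total']}/100")
        for comp in self.comparisons:
            verdict = "BELOW cut-off" if comp["below_cutoff"] else "above cut-off"
            lines.append(
                f"alpha={comp['alpha']}: predicted {comp['predicted']}, "
                f"cut-off {comp['cutoff']}, observed {self.profile['total']} "
                f"-> {verdict} (one-tailed p={comp['p_one_tailed']}, "
                f"percentile {comp['percentile']})"
            )
        if self.change is not None:
            ch = self.change
            lines.append(
                f"Retest {ch['observed_t1']} vs predicted {ch['predicted_t1']} "
                f"[{ch['lower']}, {ch['upper']}] -> {ch['verdict']}"
            )
        lines.append(f"Provenance: {json.dumps(self.provenance, sort_keys=True)}")
        return "\n".join(lines)


def build_report(
    profile: ScoreProfile,
    case: ExamineeRecord,
    model: NormativeModel,
    alphas=(0.05,),
    change_model: ChangeModel | None = None,
    retest_total: float | None = None,
    seed: int | None = None,
) -> ComparisonReport:
    """Assemble a deterministic comparison report for one examinee."""
    total = profile.total
    case_obs = ExamineeRecord(case.age, case.education, case.sex, case.cr,
                              observed_total=total)
    comparisons = []
    for alpha in alphas:
        res = single_case_test(model, case_obs, alpha=alpha)
        cut = cutoff_score(model, case_obs, alpha=alpha)
        comparisons.append(
            {
                "alpha": alpha,
                "predicted": round_half_up(res.predicted, 1),
                "cutoff": round_half_up(cut, 1),
                "discrepancy": round_half_up(res.discrepancy, 1),
                "t": round(res.t_stat, 3),
                "df": res.df,
                "p_one_tailed": round(res.p_one_tailed, 4),
                "percentile": round(res.percentile, 1),
                "below_cutoff": res.below_cutoff,
            }
        )
    change = None
    if change_model is not None:
        if retest_total is None:
            raise ValidationError("retest_total required with a change model")
        cc = classify_change(change_model, total, retest_total)
        change = {
            "predicted_t1": round_half_up(cc.predicted_t1, 1),
            "lower": round_half_up(cc.lower, 1),
            "upper": round_half_up(cc.upper, 1),
            "observed_t1": round_half_up(cc.observed_t1, 1),
            "verdict": cc.verdict,
            "alpha": cc.alpha,
        }
    provenance = {
        "package_version": __version__,
        "model_hash": _hash(model.to_dict()),
        "change_model_hash": None if change_model is None
        else _hash(change_model.to_dict()),
        "alphas": list(alphas),
        "seed": seed,
    }
    return ComparisonReport(
        examinee={"age": case.age, "education": case.education,
                  "sex": case.sex, "cr": case.cr},
        profile=profile.as_dict(),
        comparisons=comparisons,
        change=change,
        provenance=provenance,
    )
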