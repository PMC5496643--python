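"""Pipeline orchestration: ETL → rule mining → guideline audit → report.

Runs the whole analysis from the three input CSVs, writing every
intermediate artifact plus a manifest with input/output checksums so a run
can be audited and reproduced.  Identical inputs and configuration produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import arm, audit as audit_mod, etl

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; message names the stage."""


@dataclass(frozen=True)
class PipelineConfig:
    prescriptions: Path
    diagnoses: Path | None
    patients: Path | None
    out_dir: Path
    min_support: float = 0.01
    min_confidence: float = 0.50
    max_rule_items: int = 2
    rule_decimals: int = 4
    percent_decimals: int = 1
    aspirin_window_days: int = 0
    seed: int = 0
    log_level: str = "INFO"

    def validate(self, require_audit_inputs: bool = True) -> None:
        missing = [
            str(p) for p in (self.prescriptions, self.diagnoses, self.patients)
            if p is not None and not Path(p).exists()
        ]
        if require_audit_inputs and (self.diagnoses is None or self.patients is None):
            absent = [n for n, p in (("diagnoses", self.diagnoses),
                                     ("patients", self.patients)) if p is None]
            raise PipelineError(
                f"configuration: audit requested but missing input file(s): "
                f"{', '.join(absent)}"
            )
        if missing:
            raise PipelineError(f"configuration: input file(s) not found: {missing}")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def rules_to_frame(rules: Sequence[arm.AssociationRule]) -> pd.DataFrame:
    """Rule table with report-rounded statistics and exact joint counts."""
    return pd.DataFrame(
        [
            {
                "lhs": "+".join(sorted(r.lhs)),
                "rhs": "+".join(sorted(r.rhs)),
                "support": f"{r.support_r:.{r.decimals}f}",
                "confidence": f"{r.confidence_r:.{r.decimals}f}",
                "lift": f"{r.lift_r:.{r.decimals}f}",
                "support_count": r.joint_count,
            }
            for r in rules
        ],
        columns=["lhs", "rhs", "support", "confidence", "lift", "support_count"],
    )


def findings_to_frame(findings: Sequence[audit_mod.AuditFinding]) -> pd.DataFrame:
    crit_cols = ["gord_dx", "age_ge_60", "gi_complication", "aspirin",
                 "same_meal", "same_clinic"]
    rows = []
    for f in findings:
        row = {"visit_key": f.visit_key, "pattern": f.pattern,
               "drugs": "+".join(sorted(f.drugs))}
        for c in crit_cols:
            row[c] = "" if c not in f.criteria else int(f.criteria[c])
        row["verdict"] = f.verdict
        rows.append(row)
    return pd.DataFrame(rows, columns=["visit_key", "pattern", "drugs",
                                       *crit_cols, "verdict"])


def summary_to_frame(summary: audit_mod.AuditSummary) -> pd.DataFrame:
    rows = []
    for section, cats in summary.sections.items():
        for label, count in cats.items():
            pct = summary.percents.get(section, {}).get(label, 0.0)
            rows.append({"pattern": summary.pattern, "section": section,
                         "label": label, "count": count,
                         "percent": f"{pct:.1f}"})
    return pd.DataFrame(rows, columns=["pattern", "section", "label",
                                       "count", "percent"])


def render_report(
    rules: Sequence[arm.AssociationRule],
    summaries: Sequence[audit_mod.AuditSummary],
) -> str:
    """Plain-text report: numbered rule table plus audit category tables."""
    lines = ["Association rules", "=" * 17,
             f"{'no.':>4} {'LHS':<12} {'RHS':<12} {'support':>8} "
             f"{'confidence':>10} {'lift':>8}"]
    for i, r in enumerate(rules, start=1):
        lines.append(
            f"{i:>4} {'+'.join(sorted(r.lhs)):<12} {'+'.join(sorted(r.rhs)):<12} "
            f"{r.support_r:>8.4f} {r.confidence_r:>10.4f} {r.lift_r:>8.4f}"
        )
    for s in summaries:
        lines += ["", f"Audit: {s.pattern} (N = {s.total})", "-" * 30]
        for section, cats in s.sections.items():
            lines.append(f"{section}:")
            for label, count in cats.items():
                pct = s.percents.get(section, {}).get(label, 0.0)
                lines.append(f"  {label:<24} {count:>6} ({pct:.1f})")
        if s.missing_context:
            lines.append(f"  [visits without context: {s.missing_context}]")
    return "\n".join(lines) + "\n"


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute etl → mine → audit → report and write the artifact bundle.

    Returns a name → path map of all outputs.  Any stage failure removes
    partial outputs and raises :class:`PipelineError` naming the stage.
    """
    config.validate(require_audit_inputs=True)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, Path] = {}
    try:
        # --- etl ---------------------------------------------------------
        try:
            rows = etl.read_prescriptions(config.prescriptions)
            txns, omitted = etl.build_transactions(rows)
            diagnoses = pd.read_csv(config.diagnoses, dtype=str,
                                    keep_default_na=False)
            patients = pd.read_csv(config.patients, dtype=str,
                                   keep_default_na=False)
            contexts = etl.build_contexts(
                rows, diagnoses, patients,
                aspirin_window_days=config.aspirin_window_days,
            )
            outputs["transactions"] = out / "transactions.jsonl"
            etl.write_transactions_jsonl(txns, outputs["transactions"])
            outputs["contexts"] = out / "contexts.csv"
            etl.write_contexts_csv(contexts, outputs["contexts"])
            logger.info("etl: %d rows, %d patient-days omitted, %d transactions",
                        len(rows), omitted, txns.n)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - stage label added
            raise PipelineError(f"etl: {exc}") from exc

        # --- mine --------------------------------------------------------
        try:
            mcfg = arm.MiningConfig(config.min_support, config.min_confidence,
                                    config.max_rule_items, config.rule_decimals)
            rules = arm.mine(txns, mcfg) if txns.n else []
            outputs["rules"] = out / "rules.csv"
            rules_to_frame(rules).to_csv(outputs["rules"], index=False)
            logger.info("mine: %d rules at support>=%s confidence>=%s",
                        len(rules), config.min_support, config.min_confidence)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"mine: {exc}") from exc

        # --- audit -------------------------------------------------------
        summaries = []
        try:
            for pattern, finder in (
                (audit_mod.H2RA_PPI, audit_mod.find_h2ra_ppi_visits),
                (audit_mod.COX2_PPI, audit_mod.find_cox2_ppi_visits),
            ):
                findings = finder(txns, contexts)
                summary = audit_mod.summarize_audit(findings, pattern)
                summaries.append(summary)
                tag = pattern.lower()
                outputs[f"findings_{tag}"] = out / f"findings_{tag}.csv"
                findings_to_frame(findings).to_csv(outputs[f"findings_{tag}"],
                                                   index=False)
                outputs[f"summary_{tag}"] = out / f"summary_{tag}.csv"
                summary_to_frame(summary).to_csv(outputs[f"summary_{tag}"],
                                                 index=False)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"audit: {exc}") from exc

        # --- report ------------------------------------------------------
        outputs["report"] = out / "report.txt"
        outputs["report"].write_text(render_report(rules, summaries),
                                     encoding="utf-8")

        manifest = {
            "config": {
                k: str(v) if isinstance(v, Path) else v
                for k, v in dataclasses.asdict(config).items()
            },
            "inputs": {
                name: _sha256(p)
                for name, p in (("prescriptions", config.prescriptions),
                                ("diagnoses", config.diagnoses),
                                ("patients", config.patients))
                if p is not None
            },
            "stages": {
                "prescription_rows": len(rows),
                "patient_days_omitted": omitted,
                "transactions": txns.n,
                "rules": len(rules),
                "audited": {s.pattern: s.total for s in summaries},
            },
            "outputs": {},
        }
        outputs["manifest"] = out / "manifest.json"
        manifest["outputs"] = {
            name: _sha256(p) for name, p in outputs.items() if name != "manifest"
        }
        outputs["manifest"].write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        return outputs
    except Exception:
        for p in outputs.values():
            p.unlink(missing_ok=True)
        raise
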