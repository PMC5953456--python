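"""Readers, writers and report assembly.

Tables travel as delimited text (tab or comma, sniffed), reports as
JSON (full precision) or markdown/TSV (percent cells rounded to one
decimal, half away from zero, as in the published tables).  Design
labels in count files resolve against the built-in birthday designs or
a user-supplied design config mapping.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Mapping

import pandas as pd

from . import __version__
from .bayes import bf_savage_dickey_quadrature, interpret_bf
from .design import UQMDesign, birthday_design
from .estimation import SurveyCounts, estimate_table, percent
from .inference import fit_shared_prevalence, lr_test

logger = logging.getLogger("uqm")

#: Labels accepted for the two built-in birthday designs.
_BUILTIN_LABELS = {
    "one_third": "one_third",
    "two_thirds": "two_thirds",
    "p≈1/3": "one_third",
    "p≈2/3": "two_thirds",
    "p~1/3": "one_third",
    "p~2/3": "two_thirds",
}


class ParseError(ValueError):
    """A table failed validation; the message names the offending row."""


def resolve_design(label: str, design_config: Mapping | None = None) -> UQMDesign:
    """Map a text label to a design, preferring user-supplied configs."""
    if design_config and label in design_config:
        return UQMDesign.from_config({"label": label, **design_config[label]})
    key = _BUILTIN_LABELS.get(label.strip())
    if key is None:
        raise KeyError(label)
    return birthday_design(key)


def read_counts(path, design_config: Mapping | None = None) -> list[SurveyCounts]:
    """Read aggregated counts from delimited text.

    Expects a header with columns ``item, design_label, yes, no``
    (tab- or comma-separated).  An empty file yields an empty list with
    a warning; malformed rows raise :class:`ParseError` naming the row.
    """
    path = Path(path)
    if path.stat().st_size == 0:
        logger.warning("counts file %s is empty", path)
        return []
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, keep_default_na=False)
    missing = {"item", "design_label", "yes", "no"} - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    if len(df) == 0:
        logger.warning("counts file %s has a header but no rows", path)
        return []
    out = []
    for i, row in df.iterrows():
        rowno = i + 2  # header is line 1
        try:
            yes, no = int(row["yes"]), int(row["no"])
        except ValueError:
            raise ParseError(f"{path} row {rowno}: non-integer count") from None
        if yes < 0 or no < 0:
            raise ParseError(f"{path} row {rowno}: negative count {yes}/{no}")
        try:
            design = resolve_design(row["design_label"], design_config)
        except KeyError:
            raise ParseError(
                f"{path} row {rowno}: unknown design label {row['design_label']!r}"
            ) from None
        out.append(SurveyCounts(item=row["item"], design=design, yes=yes, no=no))
    return out


def write_counts(counts: list[SurveyCounts], path) -> None:
    pd.DataFrame(
        [
            {"item": c.item, "design_label": c.design.label, "yes": c.yes, "no": c.no}
            for c in counts
        ]
    ).to_csv(path, sep="\t", index=False)


_ANSWERS = {"yes": "yes", "no": "no", "": ""}


def read_respondents(path) -> pd.DataFrame:
    """Read a respondent-level table (schema of the survey simulator).

    Answers are normalized case-insensitively to {"yes", "no", ""}; a
    summary of response patterns is logged.
    """
    df = pd.read_csv(Path(path), sep=None, engine="python", keep_default_na=False)
    required = {"id", "version", "answer_first", "answer_second"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    bad_versions = set(pd.to_numeric(df["version"], errors="coerce")) - set(range(1, 9))
    if bad_versions - {None} and not all(pd.isna(v) for v in bad_versions):
        raise ParseError(f"{path}: unknown version ids {sorted(bad_versions)}")
    df["version"] = df["version"].astype(int)
    for col in ("answer_first", "answer_second"):
        norm = df[col].astype(str).str.strip().str.lower()
        unknown = set(norm) - set(_ANSWERS)
        if unknown:
            raise ParseError(f"{path}: unrecognized answers {sorted(unknown)} in {col}")
        df[col] = norm
    complete = ((df["answer_first"] != "") & (df["answer_second"] != "")).sum()
    first_only = ((df["answer_first"] != "") & (df["answer_second"] == "")).sum()
    empty = (df["answer_first"] == "").sum()
    logger.info(
        "read %d respondents: %d complete, %d first-only, %d empty",
        len(df), complete, first_only, empty,
    )
    return df


def write_respondents(table: pd.DataFrame, path, debug: bool = False) -> None:
    """Write a respondent table; latent debug columns only on request."""
    cols = ["id", "version", "answer_first", "answer_second",
            "gender", "age", "semester", "field"]
    if debug:
        cols += [c for c in table.columns if c not in cols]
    else:
        cols = [c for c in cols if c in table.columns]
    table[cols].to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# analysis report


def build_report(
    counts: list[SurveyCounts],
    seed: int | None = None,
    bayes_grid_size: int = 4001,
) -> dict:
    """Full pipeline on aggregated counts: per-condition estimates, and
    per-item LR test + pooled estimate + Savage-Dickey Bayes factor for
    items observed under two designs."""
    report: dict = {
        "metadata": {
            "package": "uqm",
            "version": __version__,
            "seed": seed,
            "designs": [c.design.to_config() for c in counts],
        },
        "estimates": estimate_table(counts),
        "items": {},
    }
    by_item: dict[str, list[SurveyCounts]] = {}
    for c in counts:
        by_item.setdefault(c.item, []).append(c)
    for item, conds in by_item.items():
        entry: dict = {}
        combined = fit_shared_prevalence(conds)
        entry["combined"] = {
            "pi_hat_pct": percent(combined.pi_hat),
            "se_pct": percent(combined.se),
            "ci_pct": [percent(combined.ci_low), percent(combined.ci_high)],
            "pi_hat": combined.pi_hat,
            "se": combined.se,
        }
        if len(conds) == 2:
            lr = lr_test(*conds)
            entry["lr"] = {
                "chi2": round(lr.chi2, 2),
                "df": lr.df,
                "p_value": round(lr.p_value, 3),
            }
            bf = bf_savage_dickey_quadrature(*conds, grid_size=bayes_grid_size)
            entry["bayes"] = {
                "bf01": round(bf.bf01, 2),
                "method": bf.method,
                "posterior_delta_mean": round(bf.posterior_delta_mean, 4),
                "posterior_delta_ci": [round(x, 4) for x in bf.posterior_delta_ci],
                "evidence_label": interpret_bf(bf.bf01),
            }
        report["items"][item] = entry
    return report


def render_report(report: dict, fmt: str = "json") -> str:
    """Serialize a report as json (lossless), markdown, or tsv."""
    if fmt == "json":
        return json.dumps(report, indent=2, default=_jsonable)
    if fmt == "tsv":
        lines = ["item\tdesign_label\tyes\tno\ta\tpi_hat_pct\tse_pct\tci_pct"]
        for r in report["estimates"]:
            lines.append(
                f"{r['item']}\t{r['design_label']}\t{r['yes']}\t{r['no']}\t"
                f"{r['a']:.3f}\t{r['pi_hat_pct']}\t{r['se_pct']}\t"
                f"{r['ci_pct'][0]}-{r['ci_pct'][1]}"
            )
        return "\n".join(lines) + "\n"
    if fmt == "markdown":
        lines = [
            "| item | design | yes | no | a | pi_hat (%) | SE (%) | 95% CI (%) |",
            "|---|---|---|---|---|---|---|---|",
        ]
        for r in report["estimates"]:
            lines.append(
                f"| {r['item']} | {r['design_label']} | {r['yes']} | {r['no']} | "
                f"{r['a']:.3f} | {r['pi_hat_pct']} | {r['se_pct']} | "
                f"{r['ci_pct'][0]}-{r['ci_pct'][1]} |"
            )
        for item, entry in report["items"].items():
            if "lr" in entry:
                lines.append(
                    f"\n{item}: chi2 = {entry['lr']['chi2']} (df {entry['lr']['df']}, "
                    f"p = {entry['lr']['p_value']}), combined "
                    f"{entry['combined']['pi_hat_pct']}%, "
                    f"BF01 = {entry['bayes']['bf01']} ({entry['bayes']['evidence_label']})"
                )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown format {fmt!r}")


def parse_report(text: str) -> dict:
    """Inverse of the json rendering (tuples become lists)."""
    return json.loads(text)


def _jsonable(obj):
    if isinstance(obj, tuple):
        return list(obj)
    try:
        return float(obj)
    except (TypeError, ValueError):
        raise TypeError(f"not JSON-serializable: {obj!r}")
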