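"""Complementation-screen tables: loading, validation, and headline counts.

Two screen schemas are supported, one per enzyme family:

* ``nadA`` — quinolinate synthase orthologs assayed in an *E. coli*
  knockout, with recovery columns for coexpressed *B. subtilis* SUF,
  coexpressed *E. coli* SUF, and anaerobic growth;
* ``ispG`` — 4-hydroxy-3-methylbut-2-enyl-diphosphate synthase orthologs,
  with recovery columns for coexpressed electron transfer proteins (ETP)
  and anaerobic growth.

Each summary count records the filter expression that produced it, so
aggregations are auditable.  The bundled reference tables (one row per
ortholog, host control included) live in :mod:`phylorep.data`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ScreenTable",
    "ScreenSummary",
    "load_screen_table",
    "load_nada_table",
    "load_ispg_table",
    "summarize_nada",
    "summarize_ispg",
    "detection_summary",
]

OUTCOME_TOKENS = {"+", "-", "partial", "NT"}
MS_TOKENS = {"+", "-", "NT", "detection_NT"}
O2_TOKENS = {"+", "-", "?"}
TEMPERATURE_TOKENS = {"mesophilic", "thermophilic", "hyperthermophilic", "?"}

_COMMON_COLUMNS = [
    "phylum",
    "species_strain",
    "complement_aerobic",
    "complement_anaerobic",
    "complemented_or_recovered",
    "tir_log10",
    "sds_page",
    "ms_detected",
    "o2_tolerance",
    "temperature_class",
    "fes_system",
    "is_host_control",
]

SCHEMAS = {
    "nadA": _COMMON_COLUMNS + ["complement_bssuf", "complement_ecsuf", "is_suf_donor"],
    "ispG": _COMMON_COLUMNS + ["complement_etp"],
}

# columns whose disjunction must equal complemented_or_recovered
_RECOVERY_COLUMNS = {
    "nadA": ["complement_aerobic", "complement_bssuf", "complement_ecsuf", "complement_anaerobic"],
    "ispG": ["complement_aerobic", "complement_etp", "complement_anaerobic"],
}


class ScreenValidationError(ValueError):
    pass


@dataclass
class ScreenTable:
    """A validated screen table plus its schema name."""

    schema: str
    frame: pd.DataFrame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def heterologous(self) -> pd.DataFrame:
        """Rows excluding the host-control ortholog."""
        return self.frame[self.frame["is_host_control"] == 0]

    @property
    def host_row(self) -> pd.DataFrame:
        return self.frame[self.frame["is_host_control"] == 1]


@dataclass
class ScreenSummary:
    """Named counts with the filter expression behind each."""

    schema: str
    counts: dict[str, int] = field(default_factory=dict)
    filters: dict[str, str] = field(default_factory=dict)

    def add(self, name: str, mask: pd.Series, expression: str) -> None:
        self.counts[name] = int(mask.sum())
        self.filters[name] = expression

    def __getitem__(self, name: str) -> int:
        return self.counts[name]

    def to_dict(self) -> dict:
        return {
            name: {"value": self.counts[name], "filter_expression": self.filters[name]}
            for name in self.counts
        }


def _positive(series: pd.Series) -> pd.Series:
    return series.isin(["+", "partial"])


def _validate(frame: pd.DataFrame, schema: str) -> pd.DataFrame:
    required = SCHEMAS[schema]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ScreenValidationError(f"missing column(s) for schema {schema}: {missing}")
    if len(frame) == 0:
        return frame

    errors: list[str] = []
    vocab = {
        "complement_aerobic": OUTCOME_TOKENS,
        "complement_anaerobic": OUTCOME_TOKENS,
        "complemented_or_recovered": {"+", "-"},
        "sds_page": {"+", "-"},
        "ms_detected": MS_TOKENS,
        "o2_tolerance": O2_TOKENS,
        "temperature_class": TEMPERATURE_TOKENS,
    }
    if schema == "nadA":
        vocab["complement_bssuf"] = OUTCOME_TOKENS
        vocab["complement_ecsuf"] = OUTCOME_TOKENS
    else:
        vocab["complement_etp"] = OUTCOME_TOKENS
    for col, allowed in vocab.items():
        bad = ~frame[col].astype(str).isin(allowed)
        for row in frame.index[bad]:
            errors.append(
                f"row {row}: column {col!r} has unknown token "
                f"{frame.loc[row, col]!r} (allowed: {sorted(allowed)})"
            )
    dup = frame["species_strain"].duplicated(keep=False)
    if dup.any():
        errors.append(
            f"duplicate species_strain values: {sorted(frame.loc[dup, 'species_strain'].unique())}"
        )
    # tir_log10: float or NT
    for row, val in frame["tir_log10"].items():
        if str(val) == "NT":
            continue
        try:
            float(val)
        except (TypeError, ValueError):
            errors.append(f"row {row}: tir_log10 must be numeric or NT, got {val!r}")
    # fes_system must name at least one scaffold system
    for row, val in frame["fes_system"].items():
        if "SufBD" not in str(val) and "IscU" not in str(val):
            errors.append(f"row {row}: fes_system {val!r} names neither SufBD nor IscU")
    # complemented_or_recovered must equal the disjunction of condition columns
    disjunction = pd.Series(False, index=frame.index)
    for col in _RECOVERY_COLUMNS[schema]:
        disjunction |= _positive(frame[col])
    mismatch = (frame["complemented_or_recovered"] == "+") != disjunction
    for row in frame.index[mismatch]:
        errors.append(
            f"row {row}: complemented_or_recovered inconsistent with condition columns"
        )
    if errors:
        raise ScreenValidationError("; ".join(errors))
    return frame


def load_screen_table(source, schema: str) -> ScreenTable:
    """Load and validate a screen TSV (path, file handle, or DataFrame)."""
    if schema not in SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}; choose from {sorted(SCHEMAS)}")
    if isinstance(source, pd.DataFrame):
        frame = source.copy()
    else:
        try:
            frame = pd.read_csv(source, sep="\t", dtype=str)
        except pd.errors.EmptyDataError as exc:
            raise ScreenValidationError("empty screen table file") from exc
    for flag in ("is_host_control", "is_suf_donor"):
        if flag in frame.columns:
            frame[flag] = frame[flag].astype(int)
    _validate(frame, schema)
    return ScreenTable(schema=schema, frame=frame.reset_index(drop=True))


def _bundled(name: str):
    return resources.files("phylorep.data").joinpath(name)


def load_nada_table() -> ScreenTable:
    """The bundled NadA reference screen (47 orthologs + host control)."""
    with resources.as_file(_bundled("table1_nada.tsv")) as path:
        return load_screen_table(path, "nadA")


def load_ispg_table() -> ScreenTable:
    """The bundled IspG reference screen (47 orthologs + host control)."""
    with resources.as_file(_bundled("table2_ispg.tsv")) as path:
        return load_screen_table(path, "ispG")


def summarize_nada(table: ScreenTable) -> ScreenSummary:
    """Headline counts of the NadA screen (host control always excluded)."""
    if table.schema != "nadA":
        raise ValueError(f"expected nadA schema, got {table.schema}")
    t = table.heterologous
    s = ScreenSummary(schema="nadA")
    aer = _positive(t["complement_aerobic"])
    ana = _positive(t["complement_anaerobic"])
    bs = _positive(t["complement_bssuf"])
    ec = _positive(t["complement_ecsuf"])
    donor = t["is_suf_donor"] == 1
    s.add("aerobic_positive", aer, "complement_aerobic == +")
    s.add("anaerobic_additional", ~aer & ana, "complement_aerobic == - and complement_anaerobic == +")
    s.add(
        "anaerobic_additional_obligate_anaerobes",
        ~aer & ana & (t["o2_tolerance"] == "-"),
        "complement_aerobic == - and complement_anaerobic == + and o2_tolerance == -",
    )
    s.add(
        "bssuf_additional",
        ~aer & bs & ~donor,
        "complement_aerobic == - and complement_bssuf == + and not is_suf_donor",
    )
    s.add("ecsuf_positive", ec, "complement_ecsuf == +")
    s.add(
        "bssuf_and_anaerobic",
        ~aer & bs & ana,
        "complement_aerobic == - and complement_bssuf == + and complement_anaerobic == +",
    )
    s.add(
        "suf_rule_violations",
        (bs | ec) & ~t["fes_system"].str.contains("SufBD"),
        "(complement_bssuf == + or complement_ecsuf == +) and SufBD not in fes_system",
    )
    return s


def summarize_ispg(table: ScreenTable) -> ScreenSummary:
    """Headline counts of the IspG screen (host control always excluded)."""
    if table.schema != "ispG":
        raise ValueError(f"expected ispG schema, got {table.schema}")
    t = table.heterologous
    s = ScreenSummary(schema="ispG")
    aer = _positive(t["complement_aerobic"])
    ana = _positive(t["complement_anaerobic"])
    etp = _positive(t["complement_etp"])
    s.add("aerobic_positive", aer, "complement_aerobic in {+, partial}")
    s.add("anaerobic_additional", ~aer & ana, "complement_aerobic == - and complement_anaerobic == +")
    s.add("etp_recovered", ~aer & etp, "complement_aerobic == - and complement_etp == +")
    return s


def detection_summary(table: ScreenTable) -> ScreenSummary:
    """Mass-spectrometry detection counts (host control excluded).

    An ortholog counts as *unrecovered* here when neither growth condition
    (aerobic or anaerobic) supported complementation: the proteomics
    cultures were grown without helper-protein coexpression, so recovery
    by coexpressed SUF or electron carriers does not bear on it.
    """
    t = table.heterologous
    s = ScreenSummary(schema=table.schema)
    analyzed = t["ms_detected"].isin(["+", "-"])
    detected = t["ms_detected"] == "+"
    unrecovered = ~_positive(t["complement_aerobic"]) & ~_positive(t["complement_anaerobic"])
    s.add("ms_analyzed", analyzed, "ms_detected in {+, -}")
    s.add("ms_detected_positive", detected, "ms_detected == +")
    s.add(
        "ms_analyzed_among_unrecovered",
        analyzed & unrecovered,
        "ms_detected in {+, -} and no complementation in aerobic or anaerobic growth",
    )
    s.add(
        "ms_detected_among_unrecovered",
        detected & unrecovered,
        "ms_detected == + and no complementation in aerobic or anaerobic growth",
    )
    return s
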