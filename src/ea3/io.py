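"""Readers and writers: appraisal tables, evidence-model configs, results.

Appraisal tables are delimited text with a header row; the first column is
the study identifier and every remaining column is one appraisal dimension
with values in [0, 1].  Evidence models (hypothesis spaces with studies, or a
causal-indicator model) are read from JSON or YAML documents whose keys
mirror the dataclass field names; validation errors name the offending key.
Machine outputs serialise floats with 17 significant digits so a write/read
round trip is lossless to full double precision.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .bayes import HypothesisSpace, IndicatorModel, StudyEvidence
from .core import AppraisalVector
from .exceptions import AppraisalValidationError, DimensionError, FormatError
from .fixtures import SurveyRecord
from .sensitivity import SweepResult

__all__ = [
    "read_appraisal_table",
    "write_appraisal_table",
    "load_evidence_config",
    "write_sweep_csv",
    "FULL_PRECISION",
]

#: printf format preserving doubles exactly across a text round trip
FULL_PRECISION = "%.17g"


def read_appraisal_table(path: str | Path) -> tuple[list[SurveyRecord], list[str]]:
    """Read a delimited appraisal table into survey records plus dimension names.

    The delimiter is sniffed by pandas (comma or tab).  Cells are validated
    as appraisals in [0, 1]; an offending cell is reported by row and column.
    """
    path = Path(path)
    try:
        # cells are kept as strings and converted with float() below, which is
        # round-trip exact; pandas' own float parser is not
        frame = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except (pd.errors.ParserError, pd.errors.EmptyDataError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse appraisal table {path}: {exc}") from exc
    if frame.shape[1] < 3:
        raise DimensionError(
            f"{path}: need an identifier column plus at least 2 appraisal "
            f"dimensions, got {frame.shape[1]} columns"
        )
    dimensions = [str(c) for c in frame.columns[1:]]
    id_col = frame.columns[0]
    records: list[SurveyRecord] = []
    for row_idx, row in frame.iterrows():
        values = []
        for dim in dimensions:
            cell = row[dim]
            try:
                value = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}: row {row_idx!r}, column {dim!r}: {cell!r} is not numeric"
                ) from None
            if not np.isfinite(value) or value < 0.0 or value > 1.0:
                raise AppraisalValidationError(
                    f"{path}: row {row_idx!r} ({row[id_col]!r}), column {dim!r}: "
                    f"value {value!r} outside [0, 1]"
                )
            values.append(value)
        records.append(
            SurveyRecord(survey_id=str(row[id_col]), appraisals=AppraisalVector(values))
        )
    return records, dimensions


def write_appraisal_table(
    records: Sequence[SurveyRecord],
    path: str | Path,
    dimensions: Sequence[str],
    id_column: str = "study_id",
) -> None:
    """Write survey records as CSV, full double precision."""
    k = len(dimensions)
    rows = []
    for record in records:
        if record.appraisals.k != k:
            raise DimensionError(
                f"survey {record.survey_id!r} has {record.appraisals.k} appraisals "
                f"for {k} dimension names"
            )
        rows.append([record.survey_id, *record.appraisals.values])
    frame = pd.DataFrame(rows, columns=[id_column, *dimensions])
    frame.to_csv(path, index=False, float_format=FULL_PRECISION)


def _key_error(context: str, key: str) -> AppraisalValidationError:
    return AppraisalValidationError(f"{context}: missing required key {key!r}")


def _get(mapping: Mapping[str, Any], key: str, context: str) -> Any:
    if not isinstance(mapping, Mapping):
        raise AppraisalValidationError(f"{context}: expected a mapping, got {type(mapping).__name__}")
    if key not in mapping:
        raise _key_error(context, key)
    return mapping[key]


def _indicator_from_dict(doc: Mapping[str, Any]) -> IndicatorModel:
    fields = (
        "p_ind_given_c",
        "p_ind_given_notc",
        "p_e_given_ind",
        "p_e_given_notind",
        "p_e_marginal",
        "prior_c",
    )
    kwargs = {}
    for name in fields:
        value = _get(doc, name, "indicator model")
        try:
            kwargs[name] = float(value)
        except (TypeError, ValueError):
            raise AppraisalValidationError(
                f"indicator model: key {name!r} has non-numeric value {value!r}"
            ) from None
    return IndicatorModel(**kwargs)


def _space_from_dict(doc: Mapping[str, Any]) -> HypothesisSpace:
    labels = _get(doc, "labels", "hypotheses")
    priors = _get(doc, "priors", "hypotheses")
    return HypothesisSpace(labels=labels, priors=priors)


def _study_from_dict(doc: Mapping[str, Any], index: int) -> StudyEvidence:
    context = f"studies[{index}]"
    return StudyEvidence(
        study_id=str(_get(doc, "study_id", context)),
        face_value_likelihoods=_get(doc, "face_value_likelihoods", context),
        marginal=float(_get(doc, "marginal", context)),
        vf=float(_get(doc, "vf", context)),
    )


def load_evidence_config(
    path: str | Path,
) -> tuple[HypothesisSpace, list[StudyEvidence]] | tuple[IndicatorModel, float]:
    """Load an evidence model from a JSON or YAML document.

    Two layouts are accepted.  A hypothesis-space document::

        {"hypotheses": {"labels": [...], "priors": [...]},
         "studies": [{"study_id": ..., "face_value_likelihoods": [...],
                      "marginal": ..., "vf": ...}, ...]}

    returns ``(HypothesisSpace, [StudyEvidence, ...])``.  An indicator
    document::

        {"indicator": {"p_ind_given_c": ..., "p_ind_given_notc": ...,
                       "p_e_given_ind": ..., "p_e_given_notind": ...,
                       "p_e_marginal": ..., "prior_c": ...},
         "vf": ...}

    returns ``(IndicatorModel, vf)``.  YAML is detected by the .yaml/.yml
    suffix; everything else is parsed as JSON.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            doc = yaml.safe_load(text)
        else:
            doc = json.loads(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(doc, Mapping):
        raise FormatError(f"{path}: top level must be a mapping")
    if "indicator" in doc:
        model = _indicator_from_dict(doc["indicator"])
        vf = float(_get(doc, "vf", "indicator config"))
        return model, vf
    if "hypotheses" in doc:
        space = _space_from_dict(doc["hypotheses"])
        studies_doc = _get(doc, "studies", "config")
        if not isinstance(studies_doc, Sequence) or len(studies_doc) == 0:
            raise AppraisalValidationError("config: key 'studies' must be a nonempty list")
        studies = [_study_from_dict(s, i) for i, s in enumerate(studies_doc)]
        return space, studies
    raise AppraisalValidationError(
        f"{path}: expected top-level key 'hypotheses' or 'indicator'"
    )


def write_sweep_csv(result: SweepResult, path: str | Path, parameter: str) -> None:
    """Write a sweep result as CSV (one row per grid point), full precision."""
    result.to_frame(parameter).to_csv(path, index=False, float_format=FULL_PRECISION)
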