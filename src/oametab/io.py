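"""Feature tables, sample sheets and compound libraries (TSV in, TSV out).

A molecular feature is an (m/z, retention time) pair with an intensity per
sample; a study ships one table per ESI polarity. The sample sheet carries
the design: biological samples have a subject and timepoint, QC injections
(pool or conditioning) have neither. Missing intensities are empty cells on
disk and NaN in memory; zero is a legitimate measured value, distinct from
missing.
"""

from __future__ import annotations

import importlib.resources
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from oametab.annotate import parse_formula, monoisotopic_mass, FormulaError

logger = logging.getLogger(__name__)

ROLES = ("biological", "qc_pool", "qc_cond", "blank")


class FormatError(ValueError):
    """Malformed input file."""


class PairingError(ValueError):
    """Paired comparison requested but subjects do not pair across timepoints."""


def _read_delimited(path, sep: str | None):
    if sep is None:
        sep = "," if str(path).endswith(".csv") else "\t"
    return pd.read_csv(path, sep=sep, comment="#", dtype={0: str})


def _header_comment(params: dict | None = None) -> str:
    from oametab import __version__

    extra = "" if not params else " " + " ".join(f"{k}={v}" for k, v in params.items())
    return f"# oametab {__version__}{extra}\n"


@dataclass
class FeatureTable:
    """Feature x sample intensity matrix with per-feature m/z and rt.

    ``features``: DataFrame indexed by feature id with columns mz, rt.
    ``intensities``: DataFrame indexed by feature id, one column per sample,
    NaN marking missing cells.
    """

    mode: str
    features: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self):
        if self.mode not in ("pos", "neg"):
            raise FormatError(f"ionization mode must be pos|neg, got {self.mode!r}")
        self.validate()

    def validate(self) -> None:
        idx = self.features.index
        if idx.duplicated().any():
            dup = idx[idx.duplicated()][0]
            raise FormatError(f"duplicate feature id {dup!r}")
        if self.intensities.columns.duplicated().any():
            dup = self.intensities.columns[self.intensities.columns.duplicated()][0]
            raise FormatError(f"duplicate sample id {dup!r}")
        if not idx.equals(self.intensities.index):
            raise FormatError("features and intensities indexes differ")
        if not (self.features["mz"] > 0).all():
            raise FormatError("all m/z values must be positive")
        if not (self.features["rt"] >= 0).all():
            raise FormatError("retention times must be non-negative")
        vals = self.intensities.to_numpy(dtype=float)
        if np.nanmin(vals, initial=np.inf) < 0:
            raise FormatError("intensities must be non-negative or missing")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.features.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_features(self) -> int:
        return len(self.features)

    @property
    def n_samples(self) -> int:
        return self.intensities.shape[1]

    def subset(self, feature_ids) -> "FeatureTable":
        ids = list(feature_ids)
        return FeatureTable(
            mode=self.mode,
            features=self.features.loc[ids].copy(),
            intensities=self.intensities.loc[ids].copy(),
        )

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.mode, self.features.copy(), self.intensities.copy())

    def write(self, path, sep: str = "\t", params: dict | None = None) -> None:
        out = self.features[["mz", "rt"]].join(self.intensities)
        out.index.name = "feature_id"
        with open(path, "w") as fh:
            fh.write(_header_comment({"mode": self.mode, **(params or {})}))
            out.to_csv(fh, sep=sep, na_rep="")


def read_feature_table(path, mode: str, sep: str | None = None) -> FeatureTable:
    """Read a delimited feature table: feature_id, mz, rt, then sample columns."""
    df = _read_delimited(path, sep)
    cols = list(df.columns)
    if len(cols) < 3 or cols[0] != "feature_id" or cols[1:3] != ["mz", "rt"]:
        raise FormatError(
            f"expected header feature_id, mz, rt, <samples...>; got {cols[:3]}"
        )
    df = df.set_index("feature_id")
    sample_cols = cols[3:]
    inten = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    # distinguish genuinely non-numeric text from empty (missing) cells
    bad = inten.isna() & df[sample_cols].notna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"non-numeric intensity at feature {df.index[r]!r}, sample {sample_cols[c]!r}"
        )
    feats = df[["mz", "rt"]].apply(pd.to_numeric, errors="raise")
    return FeatureTable(mode=mode, features=feats, intensities=inten)


@dataclass
class SampleSheet:
    """Per-sample role, subject, timepoint and injection order."""

    data: pd.DataFrame  # indexed by sample_id

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.data
        required = {"role", "subject", "timepoint", "injection_order"}
        missing = required - set(df.columns)
        if missing:
            raise FormatError(f"sample sheet missing columns {sorted(missing)}")
        if df.index.duplicated().any():
            raise FormatError("duplicate sample ids in sample sheet")
        bad_roles = set(df["role"]) - set(ROLES)
        if bad_roles:
            raise FormatError(f"unknown sample roles {sorted(bad_roles)}")
        orders = df["injection_order"]
        if orders.duplicated().any() or (orders < 1).any():
            raise FormatError("injection orders must be unique positive integers")
        bio = df[df["role"] == "biological"]
        if bio[["subject", "timepoint"]].isna().any().any():
            raise FormatError("biological samples need subject and timepoint")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def ids_with_role(self, role: str) -> list[str]:
        return list(self.data.index[self.data["role"] == role])

    @property
    def biological_ids(self) -> list[str]:
        return self.ids_with_role("biological")

    @property
    def qc_pool_ids(self) -> list[str]:
        return self.ids_with_role("qc_pool")

    @property
    def qc_cond_ids(self) -> list[str]:
        return self.ids_with_role("qc_cond")

    def pairs(self, t_early: str, t_late: str) -> pd.DataFrame:
        """Subject-paired samples: columns subject, early, late.

        Raises :class:`PairingError` unless every subject appears exactly
        once at each of the two timepoints.
        """
        bio = self.data[self.data["role"] == "biological"]
        early = bio[bio["timepoint"] == t_early]
        late = bio[bio["timepoint"] == t_late]
        for tp, sub in ((t_early, early), (t_late, late)):
            if sub["subject"].duplicated().any():
                raise PairingError(f"subject appears more than once at {tp}")
        se, sl = set(early["subject"]), set(late["subject"])
        if se != sl:
            odd = sorted(se.symmetric_difference(sl))
            raise PairingError(
                f"subjects present at only one of {t_early}/{t_late}: {odd}"
            )
        e = early.reset_index().set_index("subject")[early.index.name or "index"]
        l = late.reset_index().set_index("subject")[late.index.name or "index"]
        subjects = sorted(se)
        return pd.DataFrame(
            {"subject": subjects,
             "early": [e[s] for s in subjects],
             "late": [l[s] for s in subjects]}
        )

    def write(self, path, sep: str = "\t") -> None:
        out = self.data.copy()
        out.index.name = "sample_id"
        with open(path, "w") as fh:
            fh.write(_header_comment())
            out.to_csv(fh, sep=sep, na_rep="")


def read_sample_sheet(path, sep: str | None = None) -> SampleSheet:
    df = _read_delimited(path, sep)
    if "sample_id" not in df.columns:
        raise FormatError("sample sheet needs a sample_id column")
    df = df.set_index("sample_id")
    df["injection_order"] = pd.to_numeric(df["injection_order"], errors="raise").astype(int)
    for col in ("subject", "timepoint"):
        if col in df.columns:
            df[col] = df[col].astype("string")
    return SampleSheet(df)


@dataclass(frozen=True)
class CompoundRecord:
    name: str
    formula: str
    compound_class: str
    superclass: str
    composition: dict = field(compare=False, default_factory=dict)

    @property
    def monoisotopic_mass(self) -> float:
        return monoisotopic_mass(self.composition)


@dataclass
class CompoundLibrary:
    records: list[CompoundRecord]

    def __post_init__(self):
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            raise FormatError("compound names must be unique")

    def __len__(self) -> int:
        return len(self.records)

    def get(self, name: str) -> CompoundRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)


def load_compound_library(path, sep: str | None = None) -> CompoundLibrary:
    """Load a compound library (name, formula, class, superclass).

    Formulas are parsed eagerly so a malformed record fails at load time,
    naming the compound.
    """
    df = _read_delimited(path, sep)
    if df.empty:
        warnings.warn(f"compound library {path} is empty")
        return CompoundLibrary(records=[])
    records = []
    for row in df.itertuples(index=False):
        try:
            comp = parse_formula(row.formula)
        except FormulaError as exc:
            raise FormatError(f"compound {row.name!r}: {exc}") from exc
        records.append(
            CompoundRecord(
                name=str(row.name),
                formula=str(row.formula),
                compound_class=str(getattr(row, "compound_class", "")),
                superclass=str(getattr(row, "superclass", "")),
                composition=comp,
            )
        )
    return CompoundLibrary(records=records)


def bundled_library_path():
    """Path to the bundled 18-compound serum OA biomarker library."""
    return importlib.resources.files("oametab") / "data" / "oa18_library.tsv"


def bundled_variables_path(comparison: str):
    """Path to a bundled selected-variable list; comparison in {t28,t56,t84}."""
    comparison = comparison.lower()
    if comparison not in ("t28", "t56", "t84"):
        raise ValueError("comparison must be one of t28, t56, t84")
    return importlib.resources.files("oametab") / "data" / f"variables_{comparison}.tsv"


def load_selected_variables(comparison: str) -> pd.DataFrame:
    """Bundled VIP-selected variable list (feature_id, mz, rt, polarity, vip)."""
    df = pd.read_csv(bundled_variables_path(comparison), sep="\t", comment="#")
    df["feature_id"] = df["feature_id"].astype(str)
    return df
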