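"""Subject-level registry table with an attached codebook.

The registry table is the single currency of the pipeline: one row per
out-of-hospital cardiac-arrest (OHCA) subject, with socioeconomic position
(SEP), confounders, Utstein-style mediators and hospital outcomes, all coded
per the codebook.  Missing values are pandas NA; on disk a missing cell is an
empty string in the CSV.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

#: canonical column order and coding of the registry
DEFAULT_CODEBOOK: dict[str, dict] = {
    "sep_level": {"type": "categorical", "role": "exposure",
                  "levels": ["NHI_Q1", "NHI_Q2", "NHI_Q3", "NHI_Q4", "MA"],
                  "label": "SEP level (NHI premium quartile or Medical Aid)"},
    "sep_binary": {"type": "binary", "role": "exposure",
                   "label": "low-SEP indicator after binarization"},
    "age": {"type": "continuous", "role": "confounder", "label": "age, years"},
    "sex": {"type": "binary", "role": "confounder", "label": "male sex"},
    "diabetes": {"type": "binary", "role": "confounder", "label": "diabetes mellitus"},
    "hypertension": {"type": "binary", "role": "confounder", "label": "hypertension"},
    "metropolitan": {"type": "binary", "role": "confounder",
                     "label": "metropolitan residential region"},
    "public_location": {"type": "binary", "role": "mediator",
                        "label": "arrest in a public location"},
    "witnessed": {"type": "binary", "role": "mediator", "label": "witnessed arrest"},
    "bystander_cpr": {"type": "binary", "role": "mediator", "label": "bystander CPR"},
    "bystander_aed": {"type": "binary", "role": "mediator", "label": "bystander AED use"},
    "rti_lt8": {"type": "binary", "role": "mediator",
                "label": "EMS response time interval < 8 min"},
    "shockable": {"type": "binary", "role": "mediator",
                  "label": "initial shockable rhythm (VF/pulseless VT)"},
    "ed_level12": {"type": "binary", "role": "mediator",
                   "label": "receiving emergency department level 1-2"},
    "cag": {"type": "binary", "role": "mediator",
            "label": "coronary angiography (admitted patients)"},
    "ttm": {"type": "binary", "role": "mediator",
            "label": "targeted temperature management (admitted patients)"},
    "surv_admission": {"type": "binary", "role": "outcome",
                       "label": "survival to hospital admission"},
    "surv_discharge": {"type": "binary", "role": "outcome",
                       "label": "survival to hospital discharge"},
    "good_neuro": {"type": "binary", "role": "outcome",
                   "label": "good neurological recovery (CPC 1-2)"},
}

SEP_LEVELS = DEFAULT_CODEBOOK["sep_level"]["levels"]


@dataclass
class RegistryTable:
    """A registry data frame plus its codebook and generation metadata."""

    data: pd.DataFrame
    codebook: dict = field(default_factory=lambda: copy.deepcopy(DEFAULT_CODEBOOK))
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    def copy(self) -> "RegistryTable":
        return RegistryTable(self.data.copy(), copy.deepcopy(self.codebook),
                             copy.deepcopy(self.meta))

    def binary_columns(self) -> list[str]:
        return [c for c, info in self.codebook.items()
                if info.get("type") == "binary" and c in self.data.columns]

    def continuous_columns(self) -> list[str]:
        return [c for c, info in self.codebook.items()
                if info.get("type") == "continuous" and c in self.data.columns]

    # ------------------------------------------------------------------ io
    def to_csv(self, path: str | Path, codebook_path: str | Path | None = None) -> None:
        """Write the table as CSV (missing cell = empty string) + codebook YAML."""
        self.data.to_csv(path, index=False, na_rep="")
        if codebook_path is not None:
            with open(codebook_path, "w") as fh:
                yaml.safe_dump(self.codebook, fh, sort_keys=False)

    @classmethod
    def from_csv(cls, path: str | Path,
                 codebook_path: str | Path | None = None) -> "RegistryTable":
        if codebook_path is not None:
            with open(codebook_path) as fh:
                codebook = yaml.safe_load(fh)
        else:
            codebook = copy.deepcopy(DEFAULT_CODEBOOK)
        df = pd.read_csv(path)
        # binary columns arrive as float when they contain missing cells
        for col in df.columns:
            info = codebook.get(col, {})
            if info.get("type") == "binary":
                df[col] = df[col].astype("Float64").astype("Int8")
        return cls(df, codebook)
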