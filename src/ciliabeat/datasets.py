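"""Bundled reference data.

``load_pilot_cohort`` returns the per-patient summary table of a 34-patient
pilot cohort referred for suspected primary ciliary dyskinesia: qualitative
beat-pattern percentages (total abnormal / virtually immotile / stiff /
circular), mean ciliary dyskinesia score, the two weighted kinematic rates
(distance travelled and area swept per second), nasal NO output, and TEM
results (percentage of abnormal cilia, main ultrastructural defect, ciliary
orientation). The cohort splits 10 PCD / 15 non-PCD / 9 inconclusive under
the TEM + nasal-NO gold standard and is used throughout the test-suite and
worked examples as the reference input.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .diagnostics import GoldStandardInput, gold_standard_classify

__all__ = ["load_pilot_cohort", "gold_standard_inputs"]

# defect labels meaning "no single shared ultrastructural defect"
_NOT_SAME_DEFECT = {"No", "Heterogeneous"}


def load_pilot_cohort(derive: bool = True) -> pd.DataFrame:
    """Load the bundled 34-patient reference cohort as a DataFrame.

    With ``derive=True`` (default) two columns are added:

    * ``same_defect`` — True when the TEM phenotype is a single shared
      defect (``No``/``Heterogeneous`` labels are False);
    * ``gold_standard`` — the group recomputed from the TEM and nasal-NO
      columns via :func:`~ciliabeat.diagnostics.gold_standard_classify`
      (the published ``group`` column is retained for cross-checking).
    """
    ref = resources.files("ciliabeat").joinpath("data/pilot_cohort.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"patient_id": str})
    if derive:
        df["same_defect"] = ~df["defect_label"].isin(_NOT_SAME_DEFECT)
        df["gold_standard"] = [
            gold_standard_classify(g) for g in gold_standard_inputs(df)
        ]
    return df


def gold_standard_inputs(df: pd.DataFrame) -> list[GoldStandardInput]:
    """Build :class:`GoldStandardInput` objects from a cohort table."""
    if "same_defect" in df.columns:
        same = df["same_defect"].astype(bool)
    else:
        same = ~df["defect_label"].isin(_NOT_SAME_DEFECT)
    return [
        GoldStandardInput(
            patient_id=str(row.patient_id),
            no_n=float(row.no_n_nl_min),
            tem_pct_abnormal=float(row.tem_pct_abnormal),
            same_defect=bool(s),
        )
        for row, s in zip(df.itertuples(index=False), same)
    ]
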