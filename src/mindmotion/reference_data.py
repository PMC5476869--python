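"""Published per-participant outcomes of the eight-person telemindfulness
feasibility study (four outpatients recovering from brain injury or tumour,
four hospital employees with self-reported stress), used as input data for
the psychometric aggregation and as targets for the synthetic fixtures.

MAAS is the 15-item mean (one decimal), SWLS the 5-item sum.  MMSE was
administered to patients at entry; only patient 2 scored below the ceiling
(19 → 26 → 29 across the program).
"""

from __future__ import annotations

import pandas as pd

__all__ = ["STUDY_OUTCOMES", "outcomes_frame"]

# (participant, group, scale, before, midterm, after)
_ROWS = [
    ("patient1", "patient", "MAAS", 3.3, 2.3, 2.3),
    ("patient1", "patient", "SWLS", 16, 18, 21),
    ("patient2", "patient", "MAAS", 4.2, 4.1, 4.8),
    ("patient2", "patient", "SWLS", 16, 11, 24),
    ("patient3", "patient", "MAAS", 3.1, 3.4, 3.6),
    ("patient3", "patient", "SWLS", 17, 21, 22),
    ("patient4", "patient", "MAAS", 2.4, 2.5, 3.0),
    ("patient4", "patient", "SWLS", 24, 25, 25),
    ("employee1", "employee", "MAAS", 3.3, 2.5, 3.9),
    ("employee1", "employee", "SWLS", 28, 22, 25),
    ("employee2", "employee", "MAAS", 4.2, 3.5, 3.7),
    ("employee2", "employee", "SWLS", 25, 22, 21),
    ("employee3", "employee", "MAAS", 4.5, 4.5, 4.5),
    ("employee3", "employee", "SWLS", 25, 25, 25),
    ("employee4", "employee", "MAAS", 5.2, 4.7, 5.2),
    ("employee4", "employee", "SWLS", 31, 32, 32),
    # MMSE screening: all patients at ceiling except patient 2
    ("patient1", "patient", "MMSE", 30, None, None),
    ("patient2", "patient", "MMSE", 19, 26, 29),
    ("patient3", "patient", "MMSE", 30, None, None),
    ("patient4", "patient", "MMSE", 30, None, None),
]


def outcomes_frame() -> pd.DataFrame:
    """Tidy frame: participant, group, scale, timepoint, score."""
    records = []
    for participant, group, scale, before, midterm, after in _ROWS:
        for timepoint, score in (("before", before), ("midterm", midterm), ("after", after)):
            if score is not None:
                records.append(
                    {
                        "participant": participant,
                        "group": group,
                        "scale": scale,
                        "timepoint": timepoint,
                        "score": float(score),
                    }
                )
    return pd.DataFrame(records)


STUDY_OUTCOMES = outcomes_frame()
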