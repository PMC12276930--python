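"""Shared fixtures: compact walking sessions that exercise the full pipeline.

The "mini" protocol keeps the shape of the clinical speed profiles (constant
lead-in, then ramps between +/-20 %CWS extremes at the standard ramp slope)
but shortens the bout to 105 s so simulator/preprocessing tests stay fast.
Full-protocol sessions are built only where a test needs them.
"""

from __future__ import annotations

import numpy as np
import pytest

from gaitprop.synthgait import (SubjectSpec, TreadmillProfile, simulate_session)
from gaitprop.preprocess import preprocess_session


def mini_profile(cws: float, center_pct: float, a1: int = 1,
                 t4: float = 105.0, t1: float = 45.0) -> TreadmillProfile:
    """Clinical-shaped speed profile compressed to a short bout."""
    v2 = center_pct / 100.0 * cws
    dv = 0.2 * cws
    v1, v3 = v2 - dv, v2 + dv
    hi, lo = (v3, v1) if a1 > 0 else (v1, v3)
    kt = [0.0, t1, t1 + 15.0, t1 + 22.5, t1 + 52.5, t4]
    kv = [v2, v2, hi, hi, lo, lo]
    times = np.arange(0.0, t4 + 1e-9, 0.01)
    return TreadmillProfile(t1=t1, t4=t4, v1=v1, v2=v2, v3=v3, a1_sign=a1,
                            hold=7.5, times=times,
                            speeds=np.interp(times, kt, kv))


def mini_clinical_subject(**kw) -> SubjectSpec:
    defaults = dict(subject_id="C-mini", bodyweight=90.0, cws=0.7,
                    cohort="clinical", paretic_side="left", impairment=0.35)
    defaults.update(kw)
    return SubjectSpec(**defaults)


def mini_clinical_session(seed: int, subject: SubjectSpec | None = None,
                          centers=(70, 90, 110, 130)):
    subject = subject or mini_clinical_subject()
    plan = [(mini_profile(subject.cws, c, 1 if i % 2 == 0 else -1),
             c / 100.0 * subject.cws) for i, c in enumerate(centers)]
    return simulate_session(subject, plan, seed)


def mini_healthy_session(seed: int, subject_id: str = "H-mini",
                         speeds=(0.8, 1.0, 1.2)):
    subject = SubjectSpec(subject_id, 72.0, 1.0, "healthy")
    # cws=1.0 makes the percent-of-CWS grid coincide with absolute m/s,
    # so dv = 0.2 m/s as the healthy protocol requires
    plan = [(mini_profile(1.0, v * 100.0, 1 if i % 2 == 0 else -1), v)
            for i, v in enumerate(speeds)]
    return simulate_session(subject, plan, seed)


@pytest.fixture(scope="session")
def clin_session():
    """One compact clinical session shared across read-only tests."""
    return mini_clinical_session(seed=11)


@pytest.fixture(scope="session")
def clin_datasets(clin_session):
    """Preprocessed (both sides) compact clinical session."""
    return preprocess_session(clin_session)
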