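"""Shared fixtures.

The expensive synthetic session and its cleaned version are session-scoped
so that the cleaning, time-frequency, inverse and coupling tests can share
them.
"""

from __future__ import annotations

import numpy as np
import pytest

from alphabold import clean, inverse, io_core, synth


@pytest.fixture(scope="session")
def head():
    return inverse.HeadModel()


@pytest.fixture(scope="session")
def montage(head):
    return io_core.standard_montage(radius_mm=head.scalp_radius_mm)


@pytest.fixture(scope="session")
def electrodes(montage, head):
    eset, _ = inverse.coregister_electrodes(montage, head)
    return eset


@pytest.fixture(scope="session")
def recorded_electrodes(electrodes):
    return electrodes.subset(
        [l for l in electrodes.labels if l not in ("AFz", "FCz")]
    )


@pytest.fixture(scope="session")
def small_src(head):
    return inverse.build_source_space(200, head=head)


@pytest.fixture(scope="session")
def small_leadfield(head, small_src, recorded_electrodes):
    return inverse.compute_leadfield(head, small_src, recorded_electrodes)


@pytest.fixture(scope="session")
def session():
    """Reduced artifact-laden synthetic session (ground truth attached)."""
    return synth.simulate_session(seed=1)


@pytest.fixture(scope="session")
def cleaned_session(session):
    rec, report, decomp = clean.clean_pipeline(
        session["recording"], session["electrodes"], seed=1
    )
    return {**session, "recording": rec, "report": report, "decomp": decomp}


def make_recording(
    data: np.ndarray,
    sfreq: float = 250.0,
    labels: list[str] | None = None,
    markers=None,
) -> io_core.Recording:
    data = np.asarray(data, dtype=float)
    if labels is None:
        labels = [f"ch{i}" for i in range(data.shape[0])]
    return io_core.Recording(
        channel_labels=labels,
        sampling_rate_hz=sfreq,
        data=data,
        markers=markers or [],
    )
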