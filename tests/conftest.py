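import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from plexquant.extraction import Ms2Scan, Peak, PsmQuantRecord, match_reporter_ions
from plexquant.reference import reporter_table


@pytest.fixture
def identity_scan():
    """18 peaks exactly at the theoretical reporter m/z, good resolution."""
    peaks = [
        Peak(mz=c.exact_mz, intensity=1e4, noise=100.0, resolution=60000.0)
        for c in reporter_table()
    ]
    return Ms2Scan(scan_id="identity", peaks=peaks)


def make_record(
    psm_id="psm1",
    scan=None,
    tolerance=0.001,
    sn_per_channel=None,
    resolutions=None,
):
    """Build a PsmQuantRecord with controlled S/N and resolution values."""
    if scan is None:
        table = reporter_table()
        sn = sn_per_channel if sn_per_channel is not None else [100.0] * 18
        res = resolutions if resolutions is not None else [60000.0] * 18
        peaks = [
            Peak(mz=c.exact_mz, intensity=s * 100.0, noise=100.0, resolution=r)
            for c, s, r in zip(table, sn, res)
            if s > 0
        ]
        scan = Ms2Scan(scan_id=f"scan_{psm_id}", peaks=peaks)
    obs = match_reporter_ions(scan, tolerance)
    return PsmQuantRecord(
        psm_id=psm_id,
        scan_id=scan.scan_id,
        peptide_sequence="PEPTIDEK",
        protein_ids=("PROT1",),
        observations=obs,
    )


@pytest.fixture
def record_factory():
    return make_record
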