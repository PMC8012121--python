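import pytest

from coordchar import DiffractionPeak
from coordchar.refdata import ZN_XRD_PEAKS


@pytest.fixture
def zn_peaks() -> list[DiffractionPeak]:
    """The nine-reflection Zn(II) complex powder peak table."""
    return [DiffractionPeak(tt, fw, hkl) for tt, fw, hkl in ZN_XRD_PEAKS]
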