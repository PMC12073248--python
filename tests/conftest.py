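import base64
import struct

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def library():
    from ligandfish.feature_io import default_library

    return default_library()


@pytest.fixture(scope="session")
def library_by_name(library):
    return {record.name: record for record in library}


def _b64_doubles(values):
    return base64.b64encode(struct.pack(f"<{len(values)}d", *values)).decode()


def make_mzml(scans):
    """Build a minimal centroided mzML document from (time_min, mzs, ints) tuples."""
    blocks = []
    for idx, (time_min, mzs, ints) in enumerate(scans):
        mz64 = _b64_doubles(list(map(float, mzs)))
        int64 = _b64_doubles(list(map(float, ints)))
        blocks.append(
            f"""
  <spectrum index="{idx}" id="scan={idx + 1}" defaultArrayLength="{len(mzs)}">
    <cvParam cvRef="MS" accession="MS:1000511" name="ms level" value="1"/>
    <cvParam cvRef="MS" accession="MS:1000127" name="centroid spectrum" value=""/>
    <scanList count="1">
      <scan>
        <cvParam cvRef="MS" accession="MS:1000016" name="scan start time" value="{time_min}"
                 unitCvRef="UO" unitAccession="UO:0000031" unitName="minute"/>
      </scan>
    </scanList>
    <binaryDataArrayList count="2">
      <binaryDataArray encodedLength="{len(mz64)}">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="MS:1000514" name="m/z array" value=""/>
        <binary>{mz64}</binary>
      </binaryDataArray>
      <binaryDataArray encodedLength="{len(int64)}">
        <cvParam cvRef="MS" accession="MS:1000523" name="64-bit float" value=""/>
        <cvParam cvRef="MS" accession="MS:1000576" name="no compression" value=""/>
        <cvParam cvRef="MS" accession="MS:1000515" name="intensity array" value=""/>
        <binary>{int64}</binary>
      </binaryDataArray>
    </binaryDataArrayList>
  </spectrum>"""
        )
    return (
        '<?xml version="1.0" encoding="utf-8"?>\n'
        '<mzML xmlns="http://psi.hupo.org/ms/mzml" version="1.1.0">\n'
        f'  <run id="r1">\n    <spectrumList count="{len(scans)}">{"".join(blocks)}\n'
        "    </spectrumList>\n  </run>\n</mzML>\n"
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
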