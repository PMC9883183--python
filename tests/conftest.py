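"""Shared fixtures and independent reference implementations (oracles)."""

from __future__ import annotations

import numpy as np
import pytest

from isletseg.phantom import PhantomSpec, generate_phantom


def write_reference_edf(path, array: np.ndarray) -> None:
    """Independent minimal EDF writer used as the round-trip oracle.

    Emits the classic ESRF layout: an ASCII ``key = value ;`` header in
    braces padded to a 512-byte block, then the raw little-endian
    payload.
    """
    array = np.ascontiguousarray(array)
    dtype_names = {
        np.dtype("uint16"): "UnsignedShort",
        np.dtype("uint8"): "UnsignedByte",
        np.dtype("int32"): "SignedInteger",
        np.dtype("float32"): "FloatValue",
    }
    name = dtype_names[array.dtype]
    payload = array.astype(array.dtype.newbyteorder("<")).tobytes()
    header = (
        "{\n"
        "HeaderID = EH:000001:000000:000000 ;\n"
        f"Image = 1 ;\n"
        f"ByteOrder = LowByteFirst ;\n"
        f"DataType = {name} ;\n"
        f"Dim_1 = {array.shape[1]} ;\n"
        f"Dim_2 = {array.shape[0]} ;\n"
        f"Size = {len(payload)} ;\n"
    )
    pad = 512 - (len(header) + 2) % 512
    header = header + " " * pad + "}\n"
    assert len(header) % 512 == 0
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(payload)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230119)


@pytest.fixture(scope="session")
def small_phantom():
    """A compact phantom reused by several suites (deterministic)."""
    spec = PhantomSpec(stack_shape=(16, 96, 96), n_islets=3,
                       radius_range_px=(3, 6), z_radius_range_px=(2.5, 4),
                       seed=42)
    stack, mask, manifest = generate_phantom(spec)
    return spec, stack, mask, manifest
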