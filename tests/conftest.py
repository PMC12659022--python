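import itertools

import numpy as np
import pytest
from hypothesis import settings

import spinorder as so

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def chain6():
    return so.chain(6, j=0.5)


@pytest.fixture(scope="session")
def chain8():
    return so.chain(8, j=0.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def brute_force_vvs(n, two_s):
    """Independent enumeration oracle: filter all 2^n u/d strings."""
    out = []
    for bits in itertools.product("ud", repeat=n):
        b = 0
        ok = True
        for c in bits:
            b += 1 if c == "u" else -1
            if b < 0:
                ok = False
                break
        if ok and b == two_s:
            out.append("".join(bits))
    return out


def write_fcidump(path, norb, records, nelec=None, ms2=0):
    """Write a small synthetic FCIDUMP fixture (chemist notation)."""
    nelec = norb if nelec is None else nelec
    lines = [
        f"&FCI NORB={norb},NELEC={nelec},MS2={ms2},",
        " ORBSYM=" + ",".join(["1"] * norb) + ",",
        " ISYM=1,",
        "&END",
    ]
    lines += [f"  {v: .12E}  {i}  {j}  {k}  {l}" for v, i, j, k, l in records]
    path.write_text("\n".join(lines) + "\n")
    return path
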