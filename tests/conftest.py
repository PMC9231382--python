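import numpy as np
import pytest

from crfalign.base_scoring import PairInput
from crfalign.crf_engine import AlignmentPath
from crfalign.profile_io import AA_ORDER, SS_INDEX, ProfileHMM, ReferenceAlignment, StructuralAnnotation
from crfalign.synthetic_fixtures import SimConfig, simulate_pair


def make_profile(name: str, L: int, rng: np.random.Generator) -> ProfileHMM:
    emis = rng.dirichlet(np.full(20, 0.8), size=L)
    tr = np.tile([0.9, 0.05, 0.05, 0.6, 0.4, 0.6, 0.4], (L, 1))
    seq = "".join(AA_ORDER[k] for k in emis.argmax(axis=1))
    return ProfileHMM(name, seq, emis, tr, rng.uniform(1, 10, L))


def make_annotation(L: int, rng: np.random.Generator,
                    source: str = "observed") -> StructuralAnnotation:
    ss = "".join(rng.choice(list("HEC"), size=L))
    probs = np.zeros((L, 3))
    for k, c in enumerate(ss):
        probs[k, SS_INDEX[c]] = 1.0
    return StructuralAnnotation(ss=ss, ss_probs=probs,
                                rsa=rng.uniform(0, 1, L), source=source)


def make_pair(Ls: int, Lt: int, seed: int = 0) -> PairInput:
    rng = np.random.default_rng(seed)
    return PairInput(
        template=make_profile("tpl", Ls, rng),
        target=make_profile("tar", Lt, rng),
        template_ann=make_annotation(Ls, rng, "observed"),
        target_ann=make_annotation(Lt, rng, "predicted"),
    )


def path_from_states(states) -> AlignmentPath:
    cells = []
    i = j = 0
    for s in states:
        i += 1 if s in ("M", "D") else 0
        j += 1 if s in ("M", "I") else 0
        cells.append((i, j))
    return AlignmentPath(scheme="three_state", states=list(states),
                         cells=cells, Ls=i, Lt=j)


def reference_from_states(states) -> ReferenceAlignment:
    path = path_from_states(states)
    pairs = path.pairs
    return ReferenceAlignment(
        template_name="tpl", target_name="tar", pairs=pairs,
        template_length=path.Ls, target_length=path.Lt, path=path,
    )


def random_mid_path(rng: np.random.Generator, n_match: int = 6,
                    gap_p: float = 0.35):
    """A random M/I/D state string with no direct I<->D switches."""
    states = ["M"]
    while sum(s == "M" for s in states) < n_match:
        prev = states[-1]
        if prev == "M" and rng.random() < gap_p:
            g = "I" if rng.random() < 0.5 else "D"
            run = int(rng.integers(1, 4))
            states.extend([g] * run)
        states.append("M")
    return states


@pytest.fixture(scope="session")
def easy_pair():
    rng = np.random.default_rng(42)
    return simulate_pair(SimConfig(), rng, 0)


@pytest.fixture(scope="session")
def tiny_pair():
    rng = np.random.default_rng(43)
    cfg = SimConfig(length_min=8, length_max=12)
    return simulate_pair(cfg, rng, 1)
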