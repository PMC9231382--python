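"""Statistically controlled synthetic alignment pairs.

The generator emulates what a SABmark-style benchmark provides: for each
pair, two profile HMMs, structural annotations (observed for the template,
predicted-style for the target) and a reference alignment.  A single
concentration knob controls how similar matched profile columns are (the
"sequence identity" of the pair) and ``ss_agreement`` how often matched
residues share a secondary-structure class, so alignment difficulty is
tunable from easy to twilight-zone-like.  No evolutionary realism is
attempted: the conditional random field only needs controllable
feature-signal strength.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .base_scoring import PairInput
from .crf_engine import AlignmentPath
from .profile_io import (
    AA_ORDER,
    ProfileHMM,
    ReferenceAlignment,
    StructuralAnnotation,
    parse_annotation_table,
    parse_hhm,
    parse_reference_alignment,
    parse_ss2,
    write_alignment,
    write_annotation_table,
    write_hhm,
    write_ss2,
)

#: difficulty presets: feature-signal strength of matched columns
PRESETS: Dict[str, Dict[str, float]] = {
    "easy": dict(profile_concentration=50.0, ss_agreement=0.95,
                 gap_open=0.08, gap_extend=0.4, rsa_noise=0.05),
    "twilight": dict(profile_concentration=3.0, ss_agreement=0.65,
                     gap_open=0.15, gap_extend=0.5, rsa_noise=0.2),
}


@dataclass
class SimConfig:
    """Generator settings; the defaults are the easy preset."""

    n_pairs: int = 200
    length_min: int = 30
    length_max: int = 60
    gap_open: float = 0.08
    gap_extend: float = 0.4
    profile_concentration: float = 50.0
    ss_agreement: float = 0.95
    rsa_noise: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("gap_open", "gap_extend", "ss_agreement"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.profile_concentration <= 0:
            raise ValueError("profile_concentration must be positive")
        if self.length_min < 5:
            raise ValueError("lengths below 5 are not supported")
        if self.length_max < self.length_min:
            raise ValueError("length_max < length_min")

    @classmethod
    def preset(cls, name: str, **overrides) -> "SimConfig":
        if name not in PRESETS:
            raise ValueError(f"unknown preset {name!r}")
        return cls(**{**PRESETS[name], **overrides})


def _sample_path(cfg: SimConfig, Ls: int, rng: np.random.Generator
                 ) -> Tuple[List[str], List[Tuple[int, int]]]:
    """First-order M/I/D walk consuming exactly Ls template residues.

    Gap runs never switch directly between I and D, so every path also has a
    feasible five-state labeling.
    """
    states: List[str] = []
    i = j = 0
    prev = "M"
    while i < Ls:
        if not states:
            s = "M"
        elif prev == "I":
            s = "I" if rng.random() < cfg.gap_extend else "M"
        elif prev == "D":
            s = "D" if (rng.random() < cfg.gap_extend and i < Ls) else "M"
        else:
            u = rng.random()
            if u < cfg.gap_open:
                s = "I"
            elif u < 2 * cfg.gap_open:
                s = "D"
            else:
                s = "M"
        if s in ("M", "D"):
            i += 1
        if s in ("M", "I"):
            j += 1
        states.append(s)
        prev = s
    cells: List[Tuple[int, int]] = []
    ci = cj = 0
    for s in states:
        ci += 1 if s in ("M", "D") else 0
        cj += 1 if s in ("M", "I") else 0
        cells.append((ci, cj))
    return states, cells


def _segment_ss(L: int, rng: np.random.Generator) -> str:
    out: List[str] = []
    classes = np.array(list("HEC"))
    while len(out) < L:
        c = rng.choice(classes, p=[0.35, 0.25, 0.40])
        seg = int(rng.integers(3, 10))
        out.extend([c] * seg)
    return "".join(out[:L])


def _predicted_probs(ss: str, rng: np.random.Generator) -> np.ndarray:
    """Noisy 3-class probabilities whose argmax equals the given class."""
    from .profile_io import SS_INDEX

    L = len(ss)
    probs = np.empty((L, 3))
    for k, c in enumerate(ss):
        alpha = np.full(3, 1.5)
        alpha[SS_INDEX[c]] = 12.0
        row = rng.dirichlet(alpha)
        top = int(np.argmax(row))
        if top != SS_INDEX[c]:  # keep the drawn mass but fix the argmax
            row[top], row[SS_INDEX[c]] = row[SS_INDEX[c]], row[top]
        probs[k] = row
    return probs


def _transitions_from_path(L: int, consumed_positions: Sequence[int],
                           gap_after: Sequence[bool], insert_after: Sequence[bool]
                           ) -> np.ndarray:
    """Per-column 7-transition table reflecting the local gap structure."""
    t = np.tile(np.array([0.96, 0.02, 0.02, 0.6, 0.4, 0.6, 0.4]), (L, 1))
    for k in range(L):
        if insert_after[k]:
            t[k, :3] = [0.68, 0.30, 0.02]
        elif gap_after[k]:
            t[k, :3] = [0.68, 0.02, 0.30]
    return t


def _make_profile(name: str, emissions: np.ndarray, transitions: np.ndarray,
                  rng: np.random.Generator) -> ProfileHMM:
    L = emissions.shape[0]
    seq = "".join(AA_ORDER[k] for k in np.argmax(emissions, axis=1))
    neff = rng.uniform(1.0, 10.0, size=L)
    return ProfileHMM(name=name, sequence=seq, emissions=emissions,
                      transitions=transitions, neff=neff)


def simulate_pair(cfg: SimConfig, rng: np.random.Generator,
                  index: int = 0) -> Tuple[PairInput, ReferenceAlignment]:
    """Draw one (template, target, reference alignment) triple."""
    Ls = int(rng.integers(cfg.length_min, cfg.length_max + 1))
    while True:
        states, cells = _sample_path(cfg, Ls, rng)
        Lt = cells[-1][1]
        if Lt >= 5:
            break

    pairs = [(ci - 1, cj - 1) for s, (ci, cj) in zip(states, cells) if s == "M"]

    # emissions: matched columns share a latent distribution
    conc = cfg.profile_concentration
    tpl_emis = np.empty((Ls, 20))
    tar_emis = np.empty((Lt, 20))
    matched_t = {i: j for i, j in pairs}
    matched_q = {j: i for i, j in pairs}
    for i in range(Ls):
        latent = rng.dirichlet(np.full(20, 0.5))
        tpl_emis[i] = rng.dirichlet(conc * latent + 1e-3)
        if i in matched_t:
            tar_emis[matched_t[i]] = rng.dirichlet(conc * latent + 1e-3)
    for j in range(Lt):
        if j not in matched_q:
            latent = rng.dirichlet(np.full(20, 0.5))
            tar_emis[j] = rng.dirichlet(conc * latent + 1e-3)
    tpl_emis = np.maximum(tpl_emis, 0.0)
    tar_emis = np.maximum(tar_emis, 0.0)
    tpl_emis /= tpl_emis.sum(axis=1, keepdims=True)
    tar_emis /= tar_emis.sum(axis=1, keepdims=True)

    # secondary structure: template segments; matched targets agree with
    # probability ss_agreement; unmatched targets extend local runs
    tpl_ss = _segment_ss(Ls, rng)
    tar_ss_chars: List[str] = []
    for j in range(Lt):
        if j in matched_q:
            c = tpl_ss[matched_q[j]]
            if rng.random() >= cfg.ss_agreement:
                c = rng.choice([x for x in "HEC" if x != c])
        elif tar_ss_chars and rng.random() < 0.8:
            c = tar_ss_chars[-1]
        else:
            c = rng.choice(list("HEC"))
        tar_ss_chars.append(c)
    tar_ss = "".join(tar_ss_chars)

    tpl_rsa = rng.uniform(0.0, 1.0, size=Ls)
    tar_rsa = rng.uniform(0.0, 1.0, size=Lt)
    for i, j in pairs:
        tar_rsa[j] = np.clip(tpl_rsa[i] + rng.normal(0.0, cfg.rsa_noise), 0, 1)

    # transitions mirror the reference gap structure
    tpl_ins_after = np.zeros(Ls, dtype=bool)
    tpl_del_after = np.zeros(Ls, dtype=bool)
    tar_ins_after = np.zeros(Lt, dtype=bool)
    tar_del_after = np.zeros(Lt, dtype=bool)
    for k in range(1, len(states)):
        ci, cj = cells[k - 1]
        if states[k] == "I":
            if ci >= 1:
                tpl_ins_after[ci - 1] = True
            if cj >= 1:
                tar_del_after[cj - 1] = True
        elif states[k] == "D":
            if ci >= 1:
                tpl_del_after[ci - 1] = True
            if cj >= 1:
                tar_ins_after[cj - 1] = True
    tpl_tr = _transitions_from_path(Ls, range(Ls), tpl_del_after, tpl_ins_after)
    tar_tr = _transitions_from_path(Lt, range(Lt), tar_del_after, tar_ins_after)

    template = _make_profile(f"tpl{index:04d}", tpl_emis, tpl_tr, rng)
    target = _make_profile(f"tar{index:04d}", tar_emis, tar_tr, rng)

    onehot = np.zeros((Ls, 3))
    from .profile_io import SS_INDEX
    for k, c in enumerate(tpl_ss):
        onehot[k, SS_INDEX[c]] = 1.0
    template_ann = StructuralAnnotation(ss=tpl_ss, ss_probs=onehot,
                                        rsa=tpl_rsa, source="observed")
    tar_probs = _predicted_probs(tar_ss, rng)
    target_ann = StructuralAnnotation(ss=tar_ss, ss_probs=tar_probs,
                                      rsa=tar_rsa, source="predicted")

    pair = PairInput(template=template, target=target,
                     template_ann=template_ann, target_ann=target_ann)
    path = AlignmentPath(scheme="three_state", states=states, cells=cells,
                         Ls=Ls, Lt=Lt)
    ref = ReferenceAlignment(template_name=template.name,
                             target_name=target.name, pairs=pairs,
                             template_length=Ls, target_length=Lt, path=path)
    return pair, ref


def simulate_set(cfg: SimConfig
                 ) -> List[Tuple[PairInput, ReferenceAlignment]]:
    """Draw ``cfg.n_pairs`` pairs, deterministically under ``cfg.seed``."""
    out = []
    for k in range(cfg.n_pairs):
        rng = np.random.default_rng([cfg.seed, k])
        out.append(simulate_pair(cfg, rng, index=k))
    return out


# ---------------------------------------------------------------------------
# on-disk benchmarks
# ---------------------------------------------------------------------------


def make_benchmark(cfg: SimConfig, outdir: str, train_fraction: float = 0.75
                   ) -> str:
    """Write a train/test benchmark in the formats the aligner consumes.

    Emits per pair: template ``.hhm`` + annotation table, target ``.hhm`` +
    ``.ss2`` + predicted-accessibility table, and the gapped-FASTA reference
    alignment; plus ``manifest.tsv`` assigning each pair to the train or test
    split.  Returns the manifest path.
    """
    os.makedirs(outdir, exist_ok=True)
    n_train = int(round(train_fraction * cfg.n_pairs))
    rows = ["# name\tsplit\ttpl_hhm\ttpl_ann\ttar_hhm\ttar_ss2\ttar_acc\tref"]
    for k, (pair, ref) in enumerate(simulate_set(cfg)):
        name = f"pair{k:04d}"
        paths = {
            "tpl_hhm": f"{name}_tpl.hhm",
            "tpl_ann": f"{name}_tpl.ann",
            "tar_hhm": f"{name}_tar.hhm",
            "tar_ss2": f"{name}_tar.ss2",
            "tar_acc": f"{name}_tar.acc",
            "ref": f"{name}_ref.fasta",
        }
        with open(os.path.join(outdir, paths["tpl_hhm"]), "w") as fh:
            fh.write(write_hhm(pair.template))
        with open(os.path.join(outdir, paths["tpl_ann"]), "w") as fh:
            fh.write(write_annotation_table(pair.template_ann,
                                            pair.template.sequence))
        with open(os.path.join(outdir, paths["tar_hhm"]), "w") as fh:
            fh.write(write_hhm(pair.target))
        with open(os.path.join(outdir, paths["tar_ss2"]), "w") as fh:
            fh.write(write_ss2(pair.target_ann, pair.target.sequence))
        with open(os.path.join(outdir, paths["tar_acc"]), "w") as fh:
            fh.write(write_annotation_table(pair.target_ann,
                                            pair.target.sequence))
        with open(os.path.join(outdir, paths["ref"]), "w") as fh:
            fh.write(write_alignment(ref.path, pair.template, pair.target))
        split = "train" if k < n_train else "test"
        rows.append("\t".join([name, split] + [paths[c] for c in (
            "tpl_hhm", "tpl_ann", "tar_hhm", "tar_ss2", "tar_acc", "ref")]))
    manifest = os.path.join(outdir, "manifest.tsv")
    with open(manifest, "w") as fh:
        fh.write("\n".join(rows) + "\n")
    return manifest


def load_pair_entry(outdir: str, cols: Sequence[str]
                    ) -> Tuple[PairInput, ReferenceAlignment]:
    name, _split, tpl_hhm, tpl_ann, tar_hhm, tar_ss2, tar_acc, ref_f = cols
    with open(os.path.join(outdir, tpl_hhm)) as fh:
        template = parse_hhm(fh)
    with open(os.path.join(outdir, tpl_ann)) as fh:
        template_ann = parse_annotation_table(fh, source="observed")
    with open(os.path.join(outdir, tar_hhm)) as fh:
        target = parse_hhm(fh)
    with open(os.path.join(outdir, tar_ss2)) as fh:
        ss_ann = parse_ss2(fh)
    with open(os.path.join(outdir, tar_acc)) as fh:
        acc_ann = parse_annotation_table(fh, source="predicted")
    if len(ss_ann) != len(acc_ann):
        raise ValueError(f"pair {name}: ss2/accessibility length mismatch")
    target_ann = StructuralAnnotation(ss=ss_ann.ss, ss_probs=ss_ann.ss_probs,
                                      rsa=acc_ann.rsa, source="predicted")
    with open(os.path.join(outdir, ref_f)) as fh:
        ref = parse_reference_alignment(fh, len(template), len(target))
    pair = PairInput(template=template, target=target,
                     template_ann=template_ann, target_ann=target_ann)
    return pair, ref


def load_manifest(manifest: str, split: Optional[str] = None
                  ) -> List[Tuple[PairInput, ReferenceAlignment]]:
    """Load (pair, reference) entries from a benchmark manifest."""
    outdir = os.path.dirname(os.path.abspath(manifest))
    out = []
    with open(manifest) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if split is not None and cols[1] != split:
                continue
            out.append(load_pair_entry(outdir, cols))
    return out
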