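"""Measurement emulation: proteinogenic amino-acid labeling observed by
MS (mass-isotopomer distributions of fragments) and 2D-NMR (positional
enrichments, adjacent-pair and centre-triplet labeling fractions).

Amino acids are mapped onto their biosynthetic precursors carbon by
carbon; a fragment MID is then the (convolution) product of the
corresponding precursor EMU MIDs.  The default layout carries 193 data:
137 NMR-type plus 56 MS-type, emulating a combined LC-MS / 2D-NMR
dataset on proteinogenic amino acids.  The multiplet fine structure of
real HSQC/TOCSY spectra is approximated by pair (both-neighbours) and
triplet (centre-carbon) joint labeling fractions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .emu import EmuSystem
from .network import AtomTransitionModel, FluxDistribution

#: amino acid -> per-carbon precursor origin: (pool, 0-based atom, instance)
AA_MAPS: dict[str, list[tuple[str, int, int]]] = {
    "ala": [("pyr", 0, 0), ("pyr", 1, 0), ("pyr", 2, 0)],
    "gly": [("gly", 0, 0), ("gly", 1, 0)],
    "ser": [("ser", 0, 0), ("ser", 1, 0), ("ser", 2, 0)],
    "asp": [("oaa", 0, 0), ("oaa", 1, 0), ("oaa", 2, 0), ("oaa", 3, 0)],
    "thr": [("oaa", 0, 0), ("oaa", 1, 0), ("oaa", 2, 0), ("oaa", 3, 0)],
    "met": [("oaa", 0, 0), ("oaa", 1, 0), ("oaa", 2, 0), ("oaa", 3, 0)],
    "glu": [("akg", 0, 0), ("akg", 1, 0), ("akg", 2, 0), ("akg", 3, 0),
            ("akg", 4, 0)],
    "pro": [("akg", 0, 0), ("akg", 1, 0), ("akg", 2, 0), ("akg", 3, 0),
            ("akg", 4, 0)],
    "arg": [("akg", 0, 0), ("akg", 1, 0), ("akg", 2, 0), ("akg", 3, 0),
            ("akg", 4, 0), ("co2", 0, 0)],
    "val": [("pyr", 0, 0), ("pyr", 1, 0), ("pyr", 1, 1), ("pyr", 2, 0),
            ("pyr", 2, 1)],
    "leu": [("accoa", 0, 0), ("accoa", 1, 0), ("pyr", 1, 0), ("pyr", 1, 1),
            ("pyr", 2, 0), ("pyr", 2, 1)],
    "ile": [("oaa", 0, 0), ("oaa", 1, 0), ("pyr", 1, 0), ("oaa", 2, 0),
            ("pyr", 2, 0), ("oaa", 3, 0)],
    "his": [("r5p", 0, 0), ("r5p", 1, 0), ("r5p", 2, 0), ("r5p", 3, 0),
            ("r5p", 4, 0)],
    "phe": [("pep", 0, 0), ("pep", 1, 0), ("pep", 2, 0)],
}

#: NMR blocks: amino acid -> which data types are measured
#: E = per-carbon enrichment, P = adjacent-pair fraction, T = centre triplet
_NMR_LAYOUT = [
    ("ala", "EPT"), ("gly", "EPT"), ("ser", "EPT"), ("asp", "EPT"),
    ("thr", "EPT"), ("met", "EPT"), ("glu", "EPT"), ("pro", "EPT"),
    ("val", "EPT"), ("his", "EPT"), ("phe", "EPT"), ("ile", "EPT"),
    ("arg", "EPT"), ("leu", "EP"),
]

#: MS fragments: (amino acid, 1-based carbon range inclusive)
_MS_LAYOUT = [
    ("ala", (1, 3)), ("gly", (1, 2)), ("ser", (1, 3)), ("asp", (1, 4)),
    ("thr", (1, 4)), ("glu", (1, 5)), ("pro", (1, 5)), ("his", (1, 5)),
    ("asp", (1, 2)), ("asp", (3, 4)), ("glu", (1, 2)), ("ser", (2, 3)),
    ("ala", (2, 3)), ("gly", (2, 2)),
]


@dataclass
class NoiseModel:
    ms_sd: float = 0.004     # mol-fraction
    nmr_sd: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.ms_sd <= 0 or self.nmr_sd <= 0:
            raise ValueError("noise standard deviations must be positive")


@dataclass
class MeasurementSet:
    """Tidy table of isotopomer data: one row per datum.

    Columns: id, type (MS|NMR), aa, detail, value, sd."""
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __len__(self):
        return len(self.data)

    @property
    def n_ms(self) -> int:
        return int((self.data["type"] == "MS").sum())

    @property
    def n_nmr(self) -> int:
        return int((self.data["type"] == "NMR").sum())

    def mid(self, aa: str, frag: tuple[int, int]) -> np.ndarray:
        sel = self.data[(self.data["aa"] == aa)
                        & (self.data["detail"] == f"M{frag[0]}-{frag[1]}")]
        return sel.sort_values("bin")["value"].to_numpy()


def _aa_fragment_emus(aa: str, carbons: list[int]):
    """Group the requested amino-acid carbons by precursor instance;
    returns list of EMUs whose convolution gives the fragment MID."""
    amap = AA_MAPS[aa]
    groups: dict[tuple[str, int], list[int]] = {}
    for c in carbons:
        pool, atom, inst = amap[c]
        groups.setdefault((pool, inst), []).append(atom)
    return [(pool, tuple(sorted(atoms)))
            for (pool, _), atoms in sorted(groups.items())]


def _layout_requests():
    """All (kind, aa, detail, emu-list) rows of the default layout."""
    rows = []
    for aa, kinds in _NMR_LAYOUT:
        n = len(AA_MAPS[aa])
        if "E" in kinds:
            for c in range(n):
                rows.append(("NMR", aa, f"C{c+1}", _aa_fragment_emus(aa, [c]),
                             "last"))
        if "P" in kinds:
            for c in range(n - 1):
                rows.append(("NMR", aa, f"C{c+1}C{c+2}",
                             _aa_fragment_emus(aa, [c, c + 1]), "last"))
        if "T" in kinds:
            for c in range(1, n - 1):
                rows.append(("NMR", aa, f"C{c}C{c+1}C{c+2}",
                             _aa_fragment_emus(aa, [c - 1, c, c + 1]), "last"))
    for aa, (lo, hi) in _MS_LAYOUT:
        carbons = list(range(lo - 1, hi))
        rows.append(("MS", aa, f"M{lo}-{hi}",
                     _aa_fragment_emus(aa, carbons), "mid"))
    return rows


class MeasurementModel:
    """Maps a flux distribution to the default 193-datum layout."""

    def __init__(self, atoms: AtomTransitionModel):
        self.atoms = atoms
        self.rows = _layout_requests()
        emus = set()
        for _, _, _, elist, _ in self.rows:
            for e in elist:
                if e[0] not in ("co2", "meoh"):
                    emus.add(e)
        self.system = EmuSystem(atoms, sorted(emus))

    def ids(self) -> list[str]:
        """Datum ids in simulation order (no solve needed)."""
        out = []
        for kind, aa, detail, elist, mode in self.rows:
            if mode == "last":
                out.append(f"{kind}:{aa}:{detail}:0")
            else:
                n = sum(len(e[1]) for e in elist)
                out.extend(f"{kind}:{aa}:{detail}:{b}" for b in range(n + 1))
        return out

    def values(self, fluxes: FluxDistribution) -> np.ndarray:
        """Simulated datum values in :meth:`ids` order (lean path used by
        the fitting loop; no DataFrame construction)."""
        mids = self.system.solve(fluxes)

        def emu_mid(e):
            if e[0] in ("co2", "meoh"):
                base = self.atoms.input_mid(e[0])
                out = base
                for _ in range(len(e[1]) - 1):
                    out = np.convolve(out, base)
                return out
            return mids[e]

        vals: list[float] = []
        for kind, aa, detail, elist, mode in self.rows:
            y = emu_mid(elist[0])
            for e in elist[1:]:
                y = np.convolve(y, emu_mid(e))
            if mode == "last":
                vals.append(float(y[-1]))
            else:
                vals.extend(float(x) for x in y)
        return np.asarray(vals)

    def simulate(self, fluxes: FluxDistribution) -> pd.DataFrame:
        mids = self.system.solve(fluxes)

        def emu_mid(e):
            if e[0] in ("co2", "meoh"):
                base = self.atoms.input_mid(e[0])
                out = base
                for _ in range(len(e[1]) - 1):
                    out = np.convolve(out, base)
                return out
            return mids[e]

        recs = []
        for kind, aa, detail, elist, mode in self.rows:
            y = emu_mid(elist[0])
            for e in elist[1:]:
                y = np.convolve(y, emu_mid(e))
            if mode == "last":     # joint fully-13C fraction (scalar)
                recs.append((kind, aa, detail, 0, float(y[-1])))
            else:                  # full MID
                for b, val in enumerate(y):
                    recs.append((kind, aa, detail, b, float(val)))
        df = pd.DataFrame(recs, columns=["type", "aa", "detail", "bin",
                                         "value"])
        df.insert(0, "id", [f"{t}:{a}:{d}:{b}" for t, a, d, b
                            in zip(df["type"], df["aa"], df["detail"],
                                   df["bin"])])
        return df


def measurement_model(atoms: AtomTransitionModel, fluxes: FluxDistribution
                      ) -> MeasurementSet:
    """Noise-free measurement set for a flux distribution."""
    mm = MeasurementModel(atoms)
    df = mm.simulate(fluxes)
    df["sd"] = np.where(df["type"] == "MS", 0.004, 0.01)
    return MeasurementSet(df, meta={"noise": None})


def generate_synthetic_dataset(atoms: AtomTransitionModel,
                               fluxes: FluxDistribution,
                               noise: NoiseModel | None = None
                               ) -> MeasurementSet:
    """Simulate + measurement model + Gaussian noise (MIDs renormalized).

    Reproducible: the same seed yields an identical dataset."""
    noise = noise or NoiseModel()
    mm = MeasurementModel(atoms)
    df = mm.simulate(fluxes)
    rng = np.random.default_rng(noise.seed)
    df["sd"] = np.where(df["type"] == "MS", noise.ms_sd, noise.nmr_sd)
    noisy = df["value"].to_numpy() + rng.normal(0.0, df["sd"].to_numpy())
    df["value"] = noisy
    # renormalize MS MIDs, clip NMR scalars into [0, 1]
    ms = df["type"] == "MS"
    df.loc[ms, "value"] = df.loc[ms, "value"].clip(lower=0.0)
    for (aa, det), grp in df[ms].groupby(["aa", "detail"]):
        s = grp["value"].sum()
        if s > 0:
            df.loc[grp.index, "value"] = grp["value"] / s
    df.loc[~ms, "value"] = df.loc[~ms, "value"].clip(0.0, 1.0)
    return MeasurementSet(df, meta={"noise": noise.__dict__})
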