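"""Species parameter sets for the deoxypodophyllotoxin (DPT) whole-body PBPK model.

Each of the five built-in species (mouse, rat, monkey, dog, human) carries a
complete physiological description — tissue volumes, regional blood flows,
tissue-to-plasma partition coefficients (``K_t:pl``) — together with the
hepatic microsomal kinetic constants that drive elimination and the plasma
unbound fraction ``f_up``.

The rat is the reference species: its partition coefficients were derived
in silico from tissue composition, and every other species' ``K_t:pl`` is
obtained by assuming the *unbound* partition coefficient
``K_t:pl,u = K_t:pl / f_up`` is species-invariant, i.e.

    K_t:pl(species) = K_t:pl(rat) * f_up(species) / f_up(rat)

The brain permeability–surface-area product ``PS`` scales allometrically
from the mouse value with exponent 0.67.

Internally all volumes are mL, flows mL/min, ``PBSF`` mg microsomal protein
per body, Km in uM and Vmax in nmol/min/mg (M2) or pmol/min/mg (M7).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

__all__ = [
    "TissueEntry",
    "MetabolicParameters",
    "SpeciesProfile",
    "FlowBalanceReport",
    "SPECIES_NAMES",
    "TISSUE_NAMES",
    "PERFUSED_TISSUES",
    "DPT_MOLAR_MASS",
    "load_builtin_profile",
    "scale_ktpl_from_rat",
    "scale_ps_allometric",
    "check_flow_balance",
    "write_profile",
    "read_profile",
]

SPECIES_NAMES = ("mouse", "rat", "monkey", "dog", "human")

#: The 13 compartments of the circulatory model. ``vein``/``artery`` are
#: blood pools and carry no flow/partition entries of their own.
TISSUE_NAMES = (
    "adipose",
    "liver",
    "muscle",
    "lung",
    "kidney",
    "brain",
    "heart",
    "spleen",
    "skin",
    "gut",
    "rest_of_body",
    "vein",
    "artery",
)

#: Tissues with their own blood flow and partition coefficient.
PERFUSED_TISSUES = TISSUE_NAMES[:11]

#: Molar mass of deoxypodophyllotoxin, C22H22O7 (g/mol). Used to convert
#: mass concentrations (ug/mL) into the molar units (uM) of the microsomal
#: Km values.
DPT_MOLAR_MASS = 398.4

#: Tissues whose venous outflow returns directly to the venous pool. Gut and
#: spleen drain through the liver, so the liver row (total liver outflow)
#: represents all three; lung sits between vein and artery.
VENOUS_RETURN_TISSUES = (
    "adipose",
    "liver",
    "muscle",
    "kidney",
    "brain",
    "heart",
    "skin",
    "rest_of_body",
)


@dataclass(frozen=True)
class TissueEntry:
    """One tissue compartment: volume (mL), blood flow (mL/min), K_t:pl.

    ``blood_flow`` and ``ktpl`` are ``None`` for the vein and artery pools.
    For the liver, ``blood_flow`` is the *total* liver outflow
    (hepatic artery + gut + spleen inflows).
    """

    name: str
    volume: float
    blood_flow: float | None = None
    ktpl: float | None = None

    def __post_init__(self) -> None:
        if self.name not in TISSUE_NAMES:
            raise ValueError(f"unknown tissue {self.name!r}")
        if self.volume <= 0:
            raise ValueError(f"{self.name}: volume must be > 0")
        if self.blood_flow is not None and self.blood_flow < 0:
            raise ValueError(f"{self.name}: blood flow must be >= 0")
        if self.ktpl is not None and self.ktpl <= 0:
            raise ValueError(f"{self.name}: K_t:pl must be > 0")


@dataclass(frozen=True)
class MetabolicParameters:
    """Hepatic microsomal kinetics of DPT elimination.

    DPT is cleared by two oxidative pathways: demethylenation to M2
    (one or two Michaelis–Menten enzymes) and mono-hydroxylation to M7
    (Hill kinetics with coefficient ``m7_gamma``; auto-activation when
    gamma > 1). ``pbsf`` converts per-mg microsomal rates to whole-liver
    rates (mg total hepatic microsomal protein per body).
    """

    pbsf: float
    m2_enzymes: tuple[tuple[float, float], ...]  # (Km uM, Vmax nmol/min/mg)
    m7_km: float  # uM
    m7_vmax: float  # pmol/min/mg
    m7_gamma: float

    def __post_init__(self) -> None:
        if self.pbsf <= 0:
            raise ValueError("PBSF must be > 0")
        if not 1 <= len(self.m2_enzymes) <= 2:
            raise ValueError("m2_enzymes must hold 1 or 2 (Km, Vmax) pairs")
        for km, vmax in self.m2_enzymes:
            if km <= 0 or vmax <= 0:
                raise ValueError("M2 Km and Vmax must be > 0")
        if self.m7_km <= 0 or self.m7_vmax <= 0:
            raise ValueError("M7 Km and Vmax must be > 0")
        if self.m7_gamma < 1:
            raise ValueError("Hill coefficient must be >= 1")


@dataclass(frozen=True)
class SpeciesProfile:
    """Complete parameter set for one species.

    Attributes
    ----------
    species : str
        One of mouse, rat, monkey, dog, human.
    body_weight : float
        Reference body weight in kg.
    tissues : mapping
        ``TissueEntry`` per compartment name.
    cardiac_output : float
        Total blood flow ``Q_total`` in mL/min (equals the lung flow).
    fup : float
        Unbound fraction of DPT in plasma.
    rbp : float
        Blood-to-plasma concentration ratio (1.0 for DPT).
    ps_brain : float
        Brain permeability–surface-area product, mL/min.
    metabolic : MetabolicParameters
    mw : float
        Molar mass of DPT, g/mol.
    """

    species: str
    body_weight: float
    tissues: Mapping[str, TissueEntry]
    cardiac_output: float
    fup: float
    ps_brain: float
    metabolic: MetabolicParameters
    rbp: float = 1.0
    mw: float = DPT_MOLAR_MASS
    meta: Mapping[str, float | str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(TISSUE_NAMES) - set(self.tissues)
        if missing:
            raise ValueError(f"missing tissues: {sorted(missing)}")
        if not 0 < self.fup <= 1:
            raise ValueError("fup must lie in (0, 1]")
        if self.body_weight <= 0 or self.cardiac_output <= 0:
            raise ValueError("body weight and cardiac output must be > 0")
        if self.ps_brain <= 0:
            raise ValueError("PS must be > 0")

    def tissue(self, name: str) -> TissueEntry:
        return self.tissues[name]

    @property
    def hepatic_artery_flow(self) -> float:
        """Hepatic-artery flow Q_hep = liver outflow − gut − spleen (mL/min)."""
        t = self.tissues
        return (
            t["liver"].blood_flow
            - t["gut"].blood_flow
            - t["spleen"].blood_flow
        )

    @property
    def liver_total_flow(self) -> float:
        """Total liver inflow/outflow Q_hep + Q_gut + Q_spl (mL/min)."""
        return self.tissues["liver"].blood_flow

    def with_scaled(
        self,
        *,
        vmax_factor: float = 1.0,
        liver_flow_factor: float = 1.0,
        fup_factor: float = 1.0,
        adipose_volume_factor: float = 1.0,
    ) -> "SpeciesProfile":
        """Return a copy with multiplicative perturbations applied.

        ``liver_flow_factor`` scales the hepatic artery, gut and spleen
        flows jointly (hence the liver-row total) without rebalancing
        cardiac output.  ``fup_factor`` scales the plasma unbound fraction
        and, through the invariance of the unbound partition coefficient,
        every K_t:pl in proportion.  ``adipose_volume_factor`` resizes the
        adipose organ at constant perfusion, i.e. its blood flow scales
        with its volume.
        """

        for name, f in (
            ("vmax_factor", vmax_factor),
            ("liver_flow_factor", liver_flow_factor),
            ("fup_factor", fup_factor),
            ("adipose_volume_factor", adipose_volume_factor),
        ):
            if f <= 0:
                raise ValueError(f"{name} must be > 0")

        tissues = dict(self.tissues)
        if fup_factor != 1.0:
            for name, entry in tissues.items():
                if entry.ktpl is not None:
                    tissues[name] = replace(entry, ktpl=entry.ktpl * fup_factor)
        if adipose_volume_factor != 1.0:
            a = tissues["adipose"]
            tissues["adipose"] = replace(
                a,
                volume=a.volume * adipose_volume_factor,
                blood_flow=a.blood_flow * adipose_volume_factor,
            )
        if liver_flow_factor != 1.0:
            for name in ("liver", "gut", "spleen"):
                entry = tissues[name]
                tissues[name] = replace(
                    entry, blood_flow=entry.blood_flow * liver_flow_factor
                )
        metabolic = self.metabolic
        if vmax_factor != 1.0:
            metabolic = replace(
                metabolic,
                m2_enzymes=tuple(
                    (km, vmax * vmax_factor) for km, vmax in metabolic.m2_enzymes
                ),
                m7_vmax=metabolic.m7_vmax * vmax_factor,
            )
        fup = self.fup * fup_factor
        if fup > 1:
            raise ValueError("perturbed fup exceeds 1")
        return replace(
            self, tissues=tissues, metabolic=metabolic, fup=fup
        )


@dataclass(frozen=True)
class FlowBalanceReport:
    """Consistency check of regional flows against cardiac output."""

    species: str
    venous_return_total: float
    cardiac_output: float

    @property
    def relative_error(self) -> float:
        return abs(self.venous_return_total - self.cardiac_output) / self.cardiac_output


# ---------------------------------------------------------------------------
# Built-in parameter tables.
#
# Per species: {tissue: (volume mL, flow mL/min, Kt:pl)}. The liver row is
# the total liver outflow. Vein/artery carry volume only. Human values were
# tabulated in L and L/min and are stored here already converted to mL.
# ---------------------------------------------------------------------------

_TISSUE_TABLE: dict[str, dict[str, tuple[float, float | None, float | None]]] = {
    "rat": {
        "adipose": (19.00, 5.82, 21.63),
        "liver": (9.15, 14.53, 1.68),
        "muscle": (101.00, 23.10, 0.75),
        "lung": (1.25, 83.90, 1.72),
        "kidney": (1.83, 11.71, 1.41),
        "brain": (1.43, 1.66, 2.77),
        "heart": (0.83, 4.07, 0.97),
        "spleen": (0.50, 1.66, 1.06),
        "skin": (47.50, 4.82, 1.42),
        "gut": (6.75, 10.88, 1.00),
        "rest_of_body": (40.38, 17.36, 0.0100),
        "vein": (13.60, None, None),
        "artery": (6.80, None, None),
    },
    "mouse": {
        "adipose": (1.73, 0.72, 11.36),
        "liver": (1.10, 1.94, 0.88),
        "muscle": (7.67, 0.91, 0.40),
        "lung": (0.15, 8.00, 0.90),
        "kidney": (0.33, 1.30, 0.74),
        "brain": (0.33, 0.26, 1.46),
        "heart": (0.10, 0.28, 0.51),
        "spleen": (0.07, 0.09, 0.55),
        "skin": (3.30, 0.41, 0.75),
        "gut": (0.85, 1.50, 0.53),
        "rest_of_body": (3.39, 2.18, 0.0052),
        "vein": (0.65, None, None),
        "artery": (0.33, None, None),
    },
    "monkey": {
        "adipose": (325.89, 20.56, 3.25),
        "liver": (108.00, 144.79, 0.25),
        "muscle": (2000.00, 227.02, 0.11),
        "lung": (26.40, 893.78, 0.26),
        "kidney": (24.00, 140.32, 0.21),
        "brain": (72.00, 48.26, 0.42),
        "heart": (13.60, 43.80, 0.15),
        "spleen": (6.40, 22.34, 0.16),
        "skin": (400.00, 69.71, 0.21),
        "gut": (184.00, 79.55, 0.15),
        "rest_of_body": (546.11, 199.31, 0.0015),
        "vein": (195.73, None, None),
        "artery": (97.87, None, None),
    },
    "dog": {
        "adipose": (1500.00, 50.00, 0.64),
        "liver": (213.00, 323.33, 0.05),
        "muscle": (4250.00, 170.00, 0.02),
        "lung": (85.00, 968.33, 0.05),
        "kidney": (97.00, 170.00, 0.04),
        "brain": (50.00, 145.00, 0.08),
        "heart": (43.00, 43.33, 0.03),
        "spleen": (22.00, 13.33, 0.03),
        "skin": (364.00, 18.33, 0.04),
        "gut": (228.00, 265.00, 0.03),
        "rest_of_body": (1223.00, 48.33, 0.0003),
        "vein": (284.00, None, None),
        "artery": (141.00, None, None),
    },
    "human": {
        "adipose": (10000.0, 260.0, 26.33),
        "liver": (1690.0, 1480.0, 2.05),
        "muscle": (35000.0, 750.0, 0.92),
        "lung": (1170.0, 5600.0, 2.09),
        "kidney": (280.0, 1240.0, 1.72),
        "brain": (1450.0, 700.0, 3.37),
        "heart": (310.0, 240.0, 1.18),
        "spleen": (190.0, 80.0, 1.29),
        "skin": (7800.0, 300.0, 1.73),
        "gut": (1650.0, 1100.0, 1.22),
        "rest_of_body": (5260.0, 630.0, 0.0122),
        "vein": (3470.0, None, None),
        "artery": (1730.0, None, None),
    },
}

_BODY_WEIGHT = {"mouse": 0.02, "rat": 0.25, "monkey": 4.0, "dog": 8.5, "human": 70.0}

_FUP = {"human": 0.0656, "rat": 0.0539, "mouse": 0.0283, "monkey": 0.0081, "dog": 0.0016}

_PS_BRAIN = {"rat": 0.0133, "mouse": 0.0024, "monkey": 0.0849, "dog": 0.1407, "human": 0.5780}

_METABOLIC = {
    "mouse": MetabolicParameters(49.28, ((1.81, 3.43),), 1.21, 42.76, 1.55),
    "rat": MetabolicParameters(409.92, ((0.05, 4.93),), 1.27, 150.03, 1.55),
    "monkey": MetabolicParameters(
        5270.40, ((0.08, 0.40), (2.26, 1.02)), 0.31, 31.86, 1.78
    ),
    "dog": MetabolicParameters(
        16592.70, ((0.09, 0.03), (9.47, 0.10)), 0.52, 2.64, 1.45
    ),
    "human": MetabolicParameters(82472.00, ((0.24, 0.32),), 1.53, 24.38, 1.22),
}

#: Compound metadata recorded for reference only (feeds no computation).
_COMPOUND_META = {"logP": 2.68, "ionization": "neutral"}


def load_builtin_profile(species: str) -> SpeciesProfile:
    """Return the built-in parameter set for one of the five species.

    Raises ``KeyError`` with the list of valid names for anything else.
    """

    key = species.lower()
    if key not in SPECIES_NAMES:
        raise KeyError(
            f"unknown species {species!r}; choose one of {', '.join(SPECIES_NAMES)}"
        )
    rows = _TISSUE_TABLE[key]
    tissues = {
        name: TissueEntry(name, vol, flow, ktpl)
        for name, (vol, flow, ktpl) in rows.items()
    }
    return SpeciesProfile(
        species=key,
        body_weight=_BODY_WEIGHT[key],
        tissues=tissues,
        cardiac_output=rows["lung"][1],
        fup=_FUP[key],
        ps_brain=_PS_BRAIN[key],
        metabolic=_METABOLIC[key],
        meta=dict(_COMPOUND_META),
    )


def scale_ktpl_from_rat(
    rat_ktpl: float, fup_target: float, fup_rat: float
) -> float:
    """Scale a rat partition coefficient to another species.

    Assumes the unbound partition coefficient ``K_t:pl / f_up`` is
    species-invariant, so ``K_t:pl = K_t:pl,rat * f_up / f_up,rat``.
    """

    if rat_ktpl <= 0 or fup_target <= 0 or fup_rat <= 0:
        raise ValueError("all inputs must be > 0")
    return rat_ktpl * fup_target / fup_rat


def scale_ps_allometric(
    ps_mouse: float, weight_target: float, weight_mouse: float = 0.02
) -> float:
    """Allometric scaling of the brain PS product from the mouse value.

    ``PS_i = PS_mouse * (W_i / W_mouse)**0.67`` (mL/min).
    """

    if ps_mouse <= 0 or weight_target <= 0 or weight_mouse <= 0:
        raise ValueError("all inputs must be > 0")
    return ps_mouse * (weight_target / weight_mouse) ** 0.67


def check_flow_balance(profile: SpeciesProfile) -> FlowBalanceReport:
    """Compare the summed venous-return flows with cardiac output.

    The venous return counts the liver outflow once (the liver row) and
    excludes gut and spleen, which drain through the liver.
    """

    total = sum(
        profile.tissues[name].blood_flow for name in VENOUS_RETURN_TISSUES
    )
    return FlowBalanceReport(profile.species, total, profile.cardiac_output)


# ---------------------------------------------------------------------------
# Key-value parameter files (units are part of the key names).
# ---------------------------------------------------------------------------

def write_profile(profile: SpeciesProfile, path: str | Path) -> None:
    """Write a profile as a plain ``key = value`` parameter file."""

    lines = [
        f"species = {profile.species}",
        f"body_weight_kg = {profile.body_weight!r}",
        f"cardiac_output_ml_min = {profile.cardiac_output!r}",
        f"fup = {profile.fup!r}",
        f"rbp = {profile.rbp!r}",
        f"ps_brain_ml_min = {profile.ps_brain!r}",
        f"mw_g_mol = {profile.mw!r}",
        f"pbsf_mg = {profile.metabolic.pbsf!r}",
        f"m7_km_um = {profile.metabolic.m7_km!r}",
        f"m7_vmax_pmol_min_mg = {profile.metabolic.m7_vmax!r}",
        f"m7_gamma = {profile.metabolic.m7_gamma!r}",
    ]
    for i, (km, vmax) in enumerate(profile.metabolic.m2_enzymes, start=1):
        lines.append(f"m2_km{i}_um = {km!r}")
        lines.append(f"m2_vmax{i}_nmol_min_mg = {vmax!r}")
    for name in TISSUE_NAMES:
        t = profile.tissues[name]
        lines.append(f"tissue.{name}.volume_ml = {t.volume!r}")
        if t.blood_flow is not None:
            lines.append(f"tissue.{name}.blood_flow_ml_min = {t.blood_flow!r}")
        if t.ktpl is not None:
            lines.append(f"tissue.{name}.ktpl = {t.ktpl!r}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> SpeciesProfile:
    """Read a profile written by :func:`write_profile` (overrides allowed)."""

    kv: dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"malformed line: {raw!r}")
        key, _, value = line.partition("=")
        kv[key.strip()] = value.strip()

    def fget(key: str, default: float | None = None) -> float | None:
        if key in kv:
            return float(kv.pop(key))
        return default

    species = kv.pop("species")
    m2: list[tuple[float, float]] = []
    for i in (1, 2):
        km = fget(f"m2_km{i}_um")
        vmax = fget(f"m2_vmax{i}_nmol_min_mg")
        if km is not None and vmax is not None:
            m2.append((km, vmax))
    metabolic = MetabolicParameters(
        pbsf=fget("pbsf_mg"),
        m2_enzymes=tuple(m2),
        m7_km=fget("m7_km_um"),
        m7_vmax=fget("m7_vmax_pmol_min_mg"),
        m7_gamma=fget("m7_gamma"),
    )
    tissues = {}
    for name in TISSUE_NAMES:
        tissues[name] = TissueEntry(
            name,
            fget(f"tissue.{name}.volume_ml"),
            fget(f"tissue.{name}.blood_flow_ml_min"),
            fget(f"tissue.{name}.ktpl"),
        )
    profile = SpeciesProfile(
        species=species,
        body_weight=fget("body_weight_kg"),
        tissues=tissues,
        cardiac_output=fget("cardiac_output_ml_min"),
        fup=fget("fup"),
        ps_brain=fget("ps_brain_ml_min"),
        metabolic=metabolic,
        rbp=fget("rbp", 1.0),
        mw=fget("mw_g_mol", DPT_MOLAR_MASS),
    )
    unknown = [k for k in kv if not k.startswith("meta.")]
    if unknown:
        raise ValueError(f"unknown keys in parameter file: {unknown}")
    return profile
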