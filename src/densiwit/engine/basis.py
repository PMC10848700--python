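"""Embedded Gaussian basis sets (standard published tabulations).

Only the element/basis combinations the bundled fixtures need are included:
STO-3G for H/Li/C/N, 6-31G for H/C/N, and aug-cc-pVTZ for H.  Exponents are
in bohr^-2; contraction coefficients refer to normalized primitives.
"""

from __future__ import annotations

# Each entry: element -> list of (angular momentum letter, [(exp, coeff), ...])
# SP shells of Pople bases are stored as separate s and p shells sharing
# exponents, which is how every downstream consumer wants them anyway.

_STO3G_1S = [0.1543289673, 0.5353281423, 0.4446345422]
_STO3G_2S = [-0.09996722919, 0.3995128261, 0.7001154689]
_STO3G_2P = [0.1559162750, 0.6076837186, 0.3919573931]

STO_3G = {
    "H": [
        ("s", [(3.425250914, _STO3G_1S[0]), (0.6239137298, _STO3G_1S[1]),
               (0.1688554040, _STO3G_1S[2])]),
    ],
    "Li": [
        ("s", [(16.11957475, _STO3G_1S[0]), (2.936200663, _STO3G_1S[1]),
               (0.7946504870, _STO3G_1S[2])]),
        ("s", [(0.6362897469, _STO3G_2S[0]), (0.1478600533, _STO3G_2S[1]),
               (0.0480886784, _STO3G_2S[2])]),
        ("p", [(0.6362897469, _STO3G_2P[0]), (0.1478600533, _STO3G_2P[1]),
               (0.0480886784, _STO3G_2P[2])]),
    ],
    "C": [
        ("s", [(71.61683735, _STO3G_1S[0]), (13.04509632, _STO3G_1S[1]),
               (3.530512160, _STO3G_1S[2])]),
        ("s", [(2.941249355, _STO3G_2S[0]), (0.6834830964, _STO3G_2S[1]),
               (0.2222899159, _STO3G_2S[2])]),
        ("p", [(2.941249355, _STO3G_2P[0]), (0.6834830964, _STO3G_2P[1]),
               (0.2222899159, _STO3G_2P[2])]),
    ],
    "N": [
        ("s", [(99.10616896, _STO3G_1S[0]), (18.05231239, _STO3G_1S[1]),
               (4.885660238, _STO3G_1S[2])]),
        ("s", [(3.780455879, _STO3G_2S[0]), (0.8784966449, _STO3G_2S[1]),
               (0.2857143744, _STO3G_2S[2])]),
        ("p", [(3.780455879, _STO3G_2P[0]), (0.8784966449, _STO3G_2P[1]),
               (0.2857143744, _STO3G_2P[2])]),
    ],
}

POPLE_631G = {
    "H": [
        ("s", [(18.73113696, 0.03349460434), (2.825394365, 0.2347269535),
               (0.6401216923, 0.8137573261)]),
        ("s", [(0.1612777588, 1.0)]),
    ],
    "C": [
        ("s", [(3047.524880, 0.001834737132), (457.3695180, 0.01403732281),
               (103.9486850, 0.06884262226), (29.21015530, 0.2321844432),
               (9.286662960, 0.4679413484), (3.163926960, 0.3623119853)]),
        ("s", [(7.868272350, -0.1193324198), (1.881288540, -0.1608541517),
               (0.5442492580, 1.143456438)]),
        ("p", [(7.868272350, 0.06899906659), (1.881288540, 0.3164239610),
               (0.5442492580, 0.7443082909)]),
        ("s", [(0.1687144782, 1.0)]),
        ("p", [(0.1687144782, 1.0)]),
    ],
    "N": [
        ("s", [(4173.511460, 0.001834772160), (627.4579110, 0.01399462700),
               (142.9020930, 0.06858655181), (40.23432930, 0.2322408730),
               (13.03269830, 0.4690699481), (4.603204830, 0.3604551991)]),
        ("s", [(11.67891100, -0.1149611817), (2.917573290, -0.1691174786),
               (0.7925088600, 1.145851947)]),
        ("p", [(11.67891100, 0.06757974388), (2.917573290, 0.3239072959),
               (0.7925088600, 0.7408951398)]),
        ("s", [(0.2185415400, 1.0)]),
        ("p", [(0.2185415400, 1.0)]),
    ],
}

AUG_CC_PVTZ = {
    "H": [
        ("s", [(33.8700, 0.0060680), (5.0950, 0.0453080), (1.1590, 0.2028220)]),
        ("s", [(0.3258, 1.0)]),
        ("s", [(0.1027, 1.0)]),
        ("s", [(0.0252600, 1.0)]),
        ("p", [(1.4070, 1.0)]),
        ("p", [(0.3880, 1.0)]),
        ("p", [(0.1020000, 1.0)]),
        ("d", [(1.0570, 1.0)]),
        ("d", [(0.2470000, 1.0)]),
    ],
}

BASIS_SETS = {
    "sto-3g": STO_3G,
    "6-31g": POPLE_631G,
    "aug-cc-pvtz": AUG_CC_PVTZ,
}

_L_OF = {"s": 0, "p": 1, "d": 2, "f": 3}


def build_shells(atoms, basis_name: str, spherical: bool = True):
    """Build chem_io Shell objects for a list of AtomSite.

    Parameters
    ----------
    atoms : list of AtomSite
    basis_name : key of BASIS_SETS
    spherical : use pure (spherical-harmonic) functions for d and above
    """
    from ..chem_io import Shell

    table = BASIS_SETS[basis_name.lower()]
    shells = []
    for i, atom in enumerate(atoms):
        if atom.element not in table:
            raise KeyError(
                f"no {basis_name} data embedded for element {atom.element}")
        for letter, prims in table[atom.element]:
            exps = [e for e, _ in prims]
            coeffs = [c for _, c in prims]
            shells.append(Shell(center_index=i,
                                angular_momentum=_L_OF[letter],
                                spherical=spherical,
                                exponents=exps,
                                contraction_coeffs=coeffs))
    return shells
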