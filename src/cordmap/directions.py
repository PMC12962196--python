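"""Diffusion gradient direction table.

Thirty equally-spaced unit vectors on the hemisphere, generated once by
minimising the antipodally-symmetric electrostatic (Coulomb) energy of 30
point charges on the sphere and frozen here as a static table.  Minimum
pairwise angular separation of the shipped set is 25.6 degrees.
"""

from __future__ import annotations

import numpy as np

# fmt: off
DIRECTIONS_30: np.ndarray = np.array([
    (-0.225650591193416, +0.109830139651448, +0.967997495409056),
    (+0.237723593578505, -0.186996659862159, +0.953163019769713),
    (+0.224707400166982, +0.256366922189648, +0.940097114939304),
    (-0.222648423789144, -0.361038019103702, +0.905582259182392),
    (-0.090408619108298, +0.575091070997494, +0.813078435115509),
    (-0.606991832315163, -0.108229561848533, +0.787303802508762),
    (+0.201991018580520, -0.605837240320279, +0.769519893605040),
    (+0.642655462827541, +0.129050930368983, +0.755208456963254),
    (-0.519771321133107, +0.432927935078348, +0.736485693517764),
    (+0.630807344206290, -0.342145960456336, +0.696432506592576),
    (+0.431838192577715, +0.586651518815904, +0.685095446563620),
    (-0.219267173951192, -0.746186105573744, +0.628592238479086),
    (-0.612811792453116, -0.550725312884679, +0.566712746264342),
    (-0.831683841763674, +0.208396277837146, +0.514658118300721),
    (+0.103400945328162, +0.860048922764863, +0.499623953545304),
    (-0.366479110027022, +0.810662790612396, +0.456638699444456),
    (+0.515880751032924, -0.729912908536495, +0.448435275893300),
    (+0.782714773586281, +0.461759711373398, +0.417295521377995),
    (+0.906052204551885, -0.074736930150653, +0.416513857990734),
    (-0.892179709263112, -0.235129652433718, +0.385654525353441),
    (+0.106665107356524, -0.930191644924220, +0.351235047490701),
    (-0.750270658737726, +0.604797607293560, +0.267046424520614),
    (+0.501827266244118, +0.829883587927626, +0.243849595739515),
    (+0.827734602355117, -0.518837480245796, +0.213689253721867),
    (-0.381140455144764, -0.900321386724005, +0.210126995075376),
    (-0.762773134190867, -0.638290249414541, +0.103743449233989),
    (+0.000019734278608, +0.995938014560175, +0.090041494681594),
    (+0.965870466114997, +0.248186812189638, +0.074145457999417),
    (-0.978355566588126, +0.193723617103407, +0.072743009989954),
    (+0.472314880782289, -0.881429349521251, +0.000977340348315),
], dtype=float)
# fmt: on


def repulsion_directions(n: int = 30, seed: int = 7, iters: int = 4000,
                         lr: float = 0.05) -> np.ndarray:
    """Re-derive an equally-spaced direction set by electrostatic repulsion.

    Kept for verification of the shipped table; the pipeline always uses
    :data:`DIRECTIONS_30`.
    """
    rng = np.random.default_rng(seed)
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    for _ in range(iters):
        f = np.zeros_like(v)
        for s in (1.0, -1.0):  # antipodal symmetry
            d = v[:, None, :] - s * v[None, :, :]
            r2 = (d ** 2).sum(-1)
            np.fill_diagonal(r2, np.inf)
            f += (d / (r2 ** 1.5)[..., None]).sum(1)
        v += lr * f / n
        v /= np.linalg.norm(v, axis=1, keepdims=True)
    v[v[:, 2] < 0] *= -1
    order = np.lexsort((v[:, 1], v[:, 0], -v[:, 2]))
    return v[order]
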