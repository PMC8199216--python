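"""Independent straight-from-the-criteria oracle implementations.

Deliberately written with plain Python math (no shared code with the
package) so that detector tests compare two independent routes to the same
geometric rules. Ring normals here come from an edge cross product, valid
for the planar rings these oracles are applied to, whereas the package uses
a principal-axis fit.
"""

import math


def _dist(a, b):
    return math.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))


def _sub(a, b):
    return [x - y for x, y in zip(a, b)]


def _dot(a, b):
    return sum(x * y for x, y in zip(a, b))


def _norm(a):
    return math.sqrt(_dot(a, a))


def _cross(a, b):
    return [a[1] * b[2] - a[2] * b[1],
            a[2] * b[0] - a[0] * b[2],
            a[0] * b[1] - a[1] * b[0]]


def _centroid(pts):
    n = len(pts)
    return [sum(p[i] for p in pts) / n for i in range(3)]


def _plane_normal(ring):
    # cross product of two ring edges (planar rings only)
    v1 = _sub(ring[1], ring[0])
    v2 = _sub(ring[2], ring[0])
    n = _cross(v1, v2)
    ln = _norm(n)
    return [x / ln for x in n]


def _folded_angle_deg(n, v):
    c = abs(_dot(n, v)) / (_norm(n) * _norm(v))
    return math.degrees(math.acos(min(c, 1.0)))


def oracle_hbond(donor, hydrogen, acceptor, intramolecular=False):
    cutoff = 3.5 if intramolecular else 3.0
    if _dist(donor, acceptor) > cutoff:
        return False
    v1 = _sub(donor, hydrogen)
    v2 = _sub(acceptor, hydrogen)
    c = _dot(v1, v2) / (_norm(v1) * _norm(v2))
    angle = math.degrees(math.acos(max(-1.0, min(1.0, c))))
    return angle >= 135.0


def oracle_salt_bridge(oxygens, nitrogens):
    return min(_dist(o, n) for o in oxygens for n in nitrogens) <= 4.0


def oracle_cation_pi(cation, ring):
    cen = _centroid(ring)
    v = _sub(cation, cen)
    if _norm(v) > 6.0:
        return False
    return _folded_angle_deg(_plane_normal(ring), v) <= 45.0


def oracle_pi_pi(ring_a, ring_b, dist_cutoff=5.5, angle_cutoff=30.0):
    if _dist(_centroid(ring_a), _centroid(ring_b)) > dist_cutoff:
        return False
    return _folded_angle_deg(_plane_normal(ring_a), _plane_normal(ring_b)) <= angle_cutoff


def oracle_rmsd(A, B):
    return math.sqrt(sum(_dist(a, b) ** 2 for a, b in zip(A, B)) / len(A))
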