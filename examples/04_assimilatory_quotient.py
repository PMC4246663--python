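"""Assimilatory quotient and the nitrogen-source transition.

AQ = net CO2 fixed per net O2 released at the cell boundary.  With
ammonia as N source a pure-carbohydrate output gives AQ = 1 exactly
(CO2 + H2O -> CH2O + O2); nitrate reduction demands 4 extra NADPH per N,
evolving extra O2 and lowering AQ — more for the nitrogen-richer phloem
mix.  Rising light drives the switch from ammonia to nitrate because the
surplus reductant makes nitrate the economical sink, and the switch
begins at lower light for the phloem-producing source leaf.
"""

import leaffba as L
from leaffba.targets import CompositionTable

model = L.build_core_leaf_model()
net = model.network
biomass, phloem = model.scenarios()

carb = L.composition_to_fluxes(
    net, CompositionTable({"Suc_tx": 1.0}, label="biomass"), rate=0.5
)
c = model.constraints(carb)
t = L.find_min_photon_flux(net, c, 0.0, 1000.0, 1e-8)
sol = L.minimize_total_flux(net, c.with_photon_flux(t * 1.3))
print(f"pure carbohydrate, NH3:  AQ = {L.assimilation_quotient(sol):.6f}\n")

for label, scn in (("biomass", biomass), ("phloem", phloem)):
    aqs = {}
    for nsrc, blocked in (("NH3", ("NO3_tx",)), ("NO3", ("NH3_tx",))):
        cc = model.constraints(scn, blocked_reactions=blocked)
        tt = L.find_min_photon_flux(net, cc, 0.0, 2000.0, 1e-8)
        ss = L.minimize_total_flux(net, cc.with_photon_flux(tt * 1.01))
        aqs[nsrc] = L.assimilation_quotient(ss)
    print(f"{label:8s} AQ: {aqs['NH3']:.3f} (NH3) -> {aqs['NO3']:.3f} (NO3)")

print("\nnitrogen-source shares along the light axis (pure phloem):")
cc = model.constraints(phloem)
tt = L.find_min_photon_flux(net, cc, 0.0, 1000.0, 1e-8)
for mult in (1.001, 1.1, 1.2, 1.25, 1.5, 3.0):
    s = L.minimize_total_flux(net, cc.with_photon_flux(tt * mult))
    nh3, no3 = L.nitrogen_source_shares(s)
    print(f"  {mult:5.3f} x threshold: NH3 {nh3:5.3f}  NO3 {no3:5.3f}")
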