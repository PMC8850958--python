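"""Physical constants shared by the electromagnetic and thermal solvers."""

from dataclasses import dataclass


@dataclass(frozen=True)
class PhysicalConstants:
    """CODATA constants plus blood reference properties.

    ``rho_blood`` is fixed at 1000 kg/m^3: the perfusion literature values
    quoted in kg/(m^3 s) convert to the 1/s rates of the property tables only
    with this density.  ``cp_blood`` is the standard reference heat capacity
    of whole blood.  ``T_body`` is core body temperature (37 degC) in kelvin.
    """

    c0: float = 299_792_458.0          # speed of light in vacuum, m/s
    eps0: float = 8.8541878128e-12     # vacuum permittivity, F/m
    mu0: float = 1.25663706212e-6      # vacuum permeability, H/m
    R_gas: float = 8.314462618         # universal gas constant, J/(mol K)
    rho_blood: float = 1000.0          # kg/m^3
    cp_blood: float = 3617.0           # J/(kg K)
    T_body: float = 310.15             # K


CONSTANTS = PhysicalConstants()
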