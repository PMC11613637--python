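; synthetic AP2-like seed alignment (not a curated database alignment)
>ap2_seed_consensus
SKYRGVRQRPWGKWAAEIRDPKKAARVWLGTFDTAEEAARAYDRAALKLRGRSARLNFPDE
>ap2_seed_var1
SKYRGWRQEPWGKWAIEIRDPKKAARVWLGTFDTAEEAAREYDVAALKLRGRSARLNFPDE
>ap2_seed_var2
SVYRGVRQRPWGVIAAEIRDPKKAARVCLGTFYTAEEAARAYDRAALKLRGRSARLNFPDE
>ap2_seed_var3
SKYRGVRQRPWGKWAAEARDPKKAARIWWGTFDTAEEAARAYDRQALKGRGRSARLNFPDE
>ap2_seed_var4
SKYRGVDQRHWGKWAAEIRDPKNAERVWLGTFDTAEEAKRAYDRAALKMRGRSARLNFPDE
>ap2_seed_var5
SKYRGVRQRPWGKWAAEIYDPKKAARVWLGTFDTEEEAARAYDRAARKLRGCSARLNFPPE
>ap2_seed_var6
SKIRGIRQRPWGKWAAEIRDPKKAARVWLGTFDTAEHAARAYDRADLKLLGRSARLNFPDE
>ap2_seed_var7
SKYRGVRQRPNGKWAAEIRDPKHAKRVWLNTFDTAEEAARAYKRAALKLRGRSARENFPDE
>ap2_seed_var8
SKYRGVRQRPRGKWAAEIRDPKKAKRVWLGTFDTIEEAGRAYDRDALKLRGRSARLNFPVE
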