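el terminal pesquero
el mercado municipal
la feria libre
el parque industrial
la plaza de armas
el estadio municipal
el terminal de buses
la caleta de pescadores
el fundo El Roble
el centro comercial
la bodega central
el muelle fiscal
el embalse norte
la estación de trenes
el polígono industrial
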