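Hospital La Cisterna	un hospital
Hospital Regional de Talca	un hospital
Hospital Clínico Metropolitano	un hospital
Hospital del Trabajador	un hospital
Hospital San Borja Arriarán	un hospital
Hospital Base de Valdivia	un hospital
Clínica Alemana	una clínica
Clínica Santa María	una clínica
Clínica Bupa Reñaca	una clínica
Clínica Universidad de los Andes	una clínica
CESFAM Cardenal Silva Henríquez	un centro de salud familiar
CESFAM Violeta Parra	un centro de salud familiar
CESFAM Lo Franco	un centro de salud familiar
SAPU Maipú	un servicio de urgencia
Servicio de Urgencia HUAP	un servicio de urgencia
Posta Central	un servicio de urgencia
Agencia ACHS Rancagua	una mutualidad
Policlínico ACHS Talca	una mutualidad
Centro de Atención ACHS Puente Alto	una mutualidad
Mutual de Seguridad CChC	una mutualidad
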