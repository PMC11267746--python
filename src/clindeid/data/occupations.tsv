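gerente general	directivo
gerente de operaciones	directivo
jefe de obra	directivo
jefe de turno	directivo
jefe de bodega	directivo
administrador de local	directivo
supervisor de faena	directivo
supervisor de planta	directivo
capataz	directivo
jefe de cuadrilla	directivo
ingeniero civil	profesional
ingeniero en prevención de riesgos	profesional
ingeniero comercial	profesional
ingeniero agrónomo	profesional
enfermera	profesional
enfermero	profesional
kinesiólogo	profesional
kinesióloga	profesional
profesor	profesional
profesora	profesional
médico	profesional
médico cirujano	profesional
abogado	profesional
contador auditor	profesional
psicólogo	profesional
nutricionista	profesional
arquitecto	profesional
veterinario	profesional
periodista	profesional
trabajador social	profesional
matrona	profesional
químico farmacéutico	profesional
mecánico industrial	técnico
técnico eléctrico	técnico
técnico en enfermería	técnico
técnico paramédico	técnico
técnico electrónico	técnico
técnico en refrigeración	técnico
técnico agrícola	técnico
técnico en construcción	técnico
prevencionista de riesgos	técnico
topógrafo	técnico
programador	técnico
analista de sistemas	técnico
dibujante técnico	técnico
laboratorista	técnico
instrumentista	técnico
electromecánico	técnico
secretaria	empleado de oficina
secretario	empleado de oficina
recepcionista	empleado de oficina
cajero	empleado de oficina
cajera	empleado de oficina
administrativo	empleado de oficina
asistente administrativa	empleado de oficina
digitador	empleado de oficina
telefonista	empleado de oficina
encuestador	empleado de oficina
archivero	empleado de oficina
vendedor	trabajador de servicios
vendedora	trabajador de servicios
garzón	trabajador de servicios
garzona	trabajador de servicios
cocinero	trabajador de servicios
cocinera	trabajador de servicios
ayudante de cocina	trabajador de servicios
guardia de seguridad	trabajador de servicios
vigilante	trabajador de servicios
conserje	trabajador de servicios
peluquero	trabajador de servicios
peluquera	trabajador de servicios
auxiliar de aseo	trabajador de servicios
asesora del hogar	trabajador de servicios
cuidadora de adultos mayores	trabajador de servicios
reponedor	trabajador de servicios
promotora	trabajador de servicios
barman	trabajador de servicios
panadero	trabajador de servicios
pastelero	trabajador de servicios
carnicero	trabajador de servicios
bombero de bencinera	trabajador de servicios
trabajador agrícola	agricultor
temporero	agricultor
temporera	agricultor
fruticultor	agricultor
viñatero	agricultor
lechero	agricultor
pescador artesanal	agricultor
buzo mariscador	agricultor
trabajador forestal	agricultor
motosierrista	agricultor
apicultor	agricultor
hortalicero	agricultor
trabajador agroforestal y pesquero	agricultor
maestro carpintero	operario
carpintero	operario
albañil	operario
enfierrador	operario
soldador	operario
soldador calificado	operario
gasfiter	operario
electricista	operario
pintor de obra	operario
techador	operario
ceramista	operario
mueblista	operario
tapicero	operario
zapatero	operario
sastre	operario
modista	operario
joyero	operario
tornero	operario
matricero	operario
hojalatero	operario
vidrierista	operario
maestro de cocina de obra	operario
mecánico automotriz	operario
desabollador	operario
maestro pintor	operario
instalador sanitario	operario
operador de grúa horquilla	operador de máquinas
operador de retroexcavadora	operador de máquinas
operador de planta	operador de máquinas
conductor de camión	operador de máquinas
chofer de taxi	operador de máquinas
chofer de micro	operador de máquinas
conductor de bus	operador de máquinas
maquinista	operador de máquinas
operador de caldera	operador de máquinas
operador de envasadora	operador de máquinas
gruero	operador de máquinas
motorista	operador de máquinas
operador de montacargas	operador de máquinas
tractorista	operador de máquinas
jornal	trabajador no calificado
jornalero	trabajador no calificado
ayudante de obra	trabajador no calificado
cargador	trabajador no calificado
embalador	trabajador no calificado
recolector	trabajador no calificado
recolector de residuos	trabajador no calificado
barrendero	trabajador no calificado
lavador de autos	trabajador no calificado
estibador	trabajador no calificado
pioneta	trabajador no calificado
empaquetador	trabajador no calificado
limpiador de vidrios	trabajador no calificado
bodeguero	trabajador no calificado
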